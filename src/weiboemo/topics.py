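"""LDA topic-number selection: perplexity elbow, coherence maximum, overlap check.

Choosing the number of topics k for LDA is the procedure implemented here:

1. Fit LDA over a range of k and record the (training) perplexity curve.
   Perplexity keeps falling as k grows, so its minimum is useless; instead
   the *elbow* — the k with the maximal second-order forward difference,
   where the decrease visibly slows — is taken as an upper bound ``k_upper``.
2. Within k <= k_upper, pick the k maximizing topic coherence, a
   sliding-window NPMI statistic over each topic's top words (higher means
   the top words of a topic actually co-occur, i.e. the topic is
   interpretable).
3. Flag pairs of near-duplicate topics by Jensen-Shannon distance between
   topic-word distributions, as a diagnostic for a manual merge decision,
   together with a static 2-D intertopic map (PCA of the topic-word rows).

LDA fitting itself delegates to scikit-learn's variational implementation
with symmetric priors; the contribution of this module is the selection
procedure, which is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial.distance import jensenshannon
from sklearn.decomposition import LatentDirichletAllocation

__all__ = [
    "TopicSelection",
    "build_dtm",
    "fit_lda",
    "curves",
    "elbow",
    "select_k",
    "overlap_check",
    "topic_keywords",
    "sliding_window_coherence",
    "select_topics",
    "intertopic_plot",
]

TokenDocs = Sequence[Sequence[str]]


def build_dtm(docs: TokenDocs, min_vocab: int = 5) -> tuple[csr_matrix, list[str]]:
    """Document-term count matrix from pre-tokenized documents."""
    vocab: dict[str, int] = {}
    rows, cols, data = [], [], []
    for i, doc in enumerate(docs):
        counts: dict[int, int] = {}
        for tok in doc:
            j = vocab.setdefault(tok, len(vocab))
            counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            data.append(c)
    if len(vocab) < min_vocab:
        raise ValueError(
            f"vocabulary size {len(vocab)} below minimum {min_vocab}; "
            "not enough distinct tokens for topic modeling"
        )
    X = csr_matrix((data, (rows, cols)), shape=(len(docs), len(vocab)), dtype=np.int64)
    terms = [w for w, _ in sorted(vocab.items(), key=lambda kv: kv[1])]
    return X, terms


def fit_lda(X, k: int, seed: int, max_iter: int = 30) -> LatentDirichletAllocation:
    """Variational LDA with symmetric priors (alpha = 1/k, eta = 1/k)."""
    lda = LatentDirichletAllocation(
        n_components=k,
        doc_topic_prior=1.0 / k,
        topic_word_prior=1.0 / k,
        max_iter=max_iter,
        random_state=seed,
        learning_method="batch",
    )
    lda.fit(X)
    return lda


def _topic_word_distributions(model: LatentDirichletAllocation) -> np.ndarray:
    comp = np.asarray(model.components_, dtype=float)
    return comp / comp.sum(axis=1, keepdims=True)


def topic_keywords(
    model: LatentDirichletAllocation, terms: Sequence[str], top_n: int = 10
) -> list[list[str]]:
    """Per topic, the top_n words by in-topic probability, descending."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n > len(terms):
        warnings.warn(
            f"top_n={top_n} exceeds vocabulary size {len(terms)}; returning all terms",
            stacklevel=2,
        )
        top_n = len(terms)
    dist = _topic_word_distributions(model)
    out = []
    for row in dist:
        order = np.argsort(-row, kind="stable")[:top_n]
        out.append([terms[j] for j in order])
    return out


def sliding_window_coherence(
    topics_words: Sequence[Sequence[str]],
    docs: TokenDocs,
    window: int = 10,
    eps: float = 1e-12,
) -> float:
    """Mean NPMI coherence of topic top-word lists under sliding-window counts.

    Word and word-pair probabilities are estimated from the fraction of
    sliding windows (length ``window``, step 1) containing them; NPMI is
    averaged over all top-word pairs of each topic and then over topics.
    Word pairs that never co-occur contribute -1 (the NPMI minimum).
    """
    needed = set()
    for words in topics_words:
        needed.update(words)
    occ: dict[str, int] = {w: 0 for w in needed}
    co: dict[tuple[str, str], int] = {}
    n_windows = 0
    for doc in docs:
        toks = list(doc)
        if not toks:
            continue
        span = max(len(toks) - window + 1, 1)
        for s in range(span):
            win = set(toks[s : s + window]) & needed
            n_windows += 1
            for w in win:
                occ[w] += 1
            for w1, w2 in combinations(sorted(win), 2):
                co[(w1, w2)] = co.get((w1, w2), 0) + 1
    if n_windows == 0:
        raise ValueError("empty corpus: no windows")
    topic_scores = []
    for words in topics_words:
        pair_scores = []
        for w1, w2 in combinations(sorted(set(words)), 2):
            c12 = co.get((w1, w2), 0)
            if c12 == 0 or occ[w1] == 0 or occ[w2] == 0:
                pair_scores.append(-1.0)
                continue
            p1 = occ[w1] / n_windows
            p2 = occ[w2] / n_windows
            p12 = c12 / n_windows
            npmi = np.log((p12 + eps) / (p1 * p2)) / -np.log(p12 + eps)
            pair_scores.append(float(npmi))
        if pair_scores:
            topic_scores.append(float(np.mean(pair_scores)))
    if not topic_scores:
        raise ValueError("no scorable topic word pairs")
    return float(np.mean(topic_scores))


def curves(
    docs: TokenDocs,
    k_range: Sequence[int],
    seed: int,
    top_n: int = 10,
    window: int = 10,
    max_iter: int = 30,
    min_vocab: int = 5,
) -> tuple[list[int], list[float], list[float]]:
    """Per-k training perplexity and coherence, deterministically under seed."""
    k_values = sorted(set(int(k) for k in k_range))
    if any(k < 1 for k in k_values):
        raise ValueError("topic numbers must be >= 1")
    X, terms = build_dtm(docs, min_vocab=min_vocab)
    perplexity, coherence = [], []
    for k in k_values:
        model = fit_lda(X, k, seed, max_iter=max_iter)
        perplexity.append(float(model.perplexity(X)))
        words = topic_keywords(model, terms, top_n=min(top_n, len(terms)))
        coherence.append(sliding_window_coherence(words, docs, window=window))
    return k_values, perplexity, coherence


def elbow(perplexity: Sequence[float], k_values: Sequence[int] | None = None) -> int:
    """Upper bound on k: the point of maximal positive second-order difference.

    The second forward difference is taken on the *log* of the perplexity,
    i.e. on per-token cross-entropy.  Perplexity tends to fall geometrically
    with k, which makes raw second differences peak at the start of the curve
    regardless of where the decrease actually slows; on the log scale a
    geometric decline is linear and the turn stands out as the curvature
    maximum.  A curve with no positive curvature (flat or linear decline)
    has no turn; the maximum k is returned with a warning.
    """
    p = list(perplexity)
    if len(p) < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    if any(x <= 0 for x in p):
        raise ValueError("perplexity values must be positive")
    if k_values is None:
        k_values = list(range(1, len(p) + 1))
    k_values = list(k_values)
    lp = np.log(p)
    d2 = [lp[i - 1] - 2 * lp[i] + lp[i + 1] for i in range(1, len(p) - 1)]
    best = int(np.argmax(d2))
    if d2[best] <= 0:
        warnings.warn("no turn in perplexity curve; using maximum k", stacklevel=2)
        return k_values[-1]
    return k_values[best + 1]


def select_k(
    coherence: Sequence[float],
    k_upper: int,
    k_values: Sequence[int] | None = None,
) -> int:
    """Coherence-maximizing k restricted to k <= k_upper; ties prefer smaller k."""
    c = list(coherence)
    if k_values is None:
        k_values = list(range(1, len(c) + 1))
    k_values = list(k_values)
    if k_upper not in k_values:
        raise ValueError(f"k_upper={k_upper} outside evaluated range {k_values}")
    candidates = [(kv, cv) for kv, cv in zip(k_values, c) if kv <= k_upper]
    best_k, best_c = candidates[0]
    for kv, cv in candidates[1:]:
        if cv > best_c + 1e-12:
            best_k, best_c = kv, cv
    return best_k


def overlap_check(
    model: LatentDirichletAllocation, threshold: float = 0.25
) -> list[tuple[int, int, float]]:
    """Topic pairs (0-based) whose word distributions nearly coincide.

    Pairs with Jensen-Shannon distance (base 2) below ``threshold`` are
    reported for a manual merge decision; identical topics give distance 0.
    """
    dist = _topic_word_distributions(model)
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 topics")
    pairs = []
    for i, j in combinations(range(dist.shape[0]), 2):
        d = float(jensenshannon(dist[i], dist[j], base=2))
        if np.isnan(d):
            d = 0.0
        if d < threshold:
            pairs.append((i, j, d))
    return pairs


@dataclass
class TopicSelection:
    """Result of the full selection pipeline."""

    k_values: list[int]
    perplexity: list[float]
    coherence: list[float]
    k_upper: int
    k_best: int
    overlap_pairs: list[tuple[int, int, float]]
    keywords: list[list[str]]
    model: LatentDirichletAllocation = field(repr=False, default=None)
    terms: list[str] = field(repr=False, default_factory=list)

    def as_dict(self) -> dict:
        return {
            "k_values": self.k_values,
            "perplexity": self.perplexity,
            "coherence": self.coherence,
            "k_upper": self.k_upper,
            "k_best": self.k_best,
            "overlap_pairs": [list(p) for p in self.overlap_pairs],
            "keywords": self.keywords,
        }


def select_topics(
    docs: TokenDocs,
    k_range: Sequence[int],
    seed: int,
    top_n: int = 10,
    window: int = 10,
    overlap_threshold: float = 0.25,
    max_iter: int = 30,
    min_vocab: int = 5,
) -> TopicSelection:
    """Run the whole pipeline: curves -> elbow -> coherence argmax -> overlap."""
    k_values, perp, coh = curves(
        docs, k_range, seed, top_n=top_n, window=window, max_iter=max_iter,
        min_vocab=min_vocab,
    )
    k_upper = elbow(perp, k_values)
    k_best = select_k(coh, k_upper, k_values)
    X, terms = build_dtm(docs, min_vocab=min_vocab)
    model = fit_lda(X, k_best, seed, max_iter=max_iter)
    pairs = overlap_check(model, overlap_threshold) if k_best >= 2 else []
    words = topic_keywords(model, terms, top_n=min(top_n, len(terms)))
    return TopicSelection(
        k_values=k_values,
        perplexity=perp,
        coherence=coh,
        k_upper=k_upper,
        k_best=k_best,
        overlap_pairs=pairs,
        keywords=words,
        model=model,
        terms=terms,
    )


def intertopic_plot(model: LatentDirichletAllocation, path: str) -> None:
    """Static 2-D intertopic map: PCA of topic-word rows, marker area ~ topic mass."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.decomposition import PCA

    dist = _topic_word_distributions(model)
    k = dist.shape[0]
    if k >= 2:
        xy = PCA(n_components=2).fit_transform(dist)
    else:
        xy = np.zeros((k, 2))
    mass = np.asarray(model.components_).sum(axis=1)
    mass = mass / mass.sum()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xy[:, 0], xy[:, 1], s=3000 * mass, alpha=0.5)
    for i, (x, y) in enumerate(xy):
        ax.annotate(str(i + 1), (x, y), ha="center", va="center")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("Intertopic distance map (PCA)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
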