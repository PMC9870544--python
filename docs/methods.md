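# Methods

## The classification procedure

`weiboemo` implements a deterministic, rule-based emotion classifier for
short Chinese social-media texts. There is no training step; everything is
driven by an affective lexicon in the DLUT style (word, fine-grained
category code, intensity `q`, polarity), a degree-adverb table, and a
negation list.

**Sentence position weights.** Posts are split at `。！？!?；` plus newline
(configurable; Weibo punctuation is inconsistent, so the set errs broad).
For `n ≤ 2` sentences weights are uniform `1/n`; for `n > 2` the first and
last sentences get `2/(n+2)` and interior ones `1/(n+2)`. The weights sum to
1 for every `n` (algebraically `(2·2 + (n−2))/(n+2) = 1`), so a post's score
scale does not depend on its length.

**Emotion units.** Every lexicon hit anchors a unit scoring
`e_j = (−1)^m · Π c_v · q` with `m` attached negations and degree factors
`c_v`. The formula is order-free: 很不好 and 不很好 score identically. The
published formulation leaves modifier attachment to a dependency parse; the
package accepts any parser through the `ParserAdapter` hook but defaults to
a window rule — the up-to-3 tokens immediately preceding the emotion word,
stopping at clause boundaries (`，、,:：;`). The window reproduces standard
lexicon-method practice and is exact on the synthetic corpora; a parser
failure falls back to the window with a logged warning rather than dropping
the sentence.

**Bidirectional conversion.** A negative unit score expresses the reverse
emotion and is reassigned to the paired opposite category
(good↔disgust, joy↔sadness, anger↔fear, surprise↔anticipate) with the
absolute score. Conversion is applied **per unit, before summation**, so
sentence vectors are always nonnegative and well-defined even when units of
the same category disagree in sign. (Applying it per sentence instead would
make the vector depend on cancellation order; the per-unit choice is this
package's, not a claim about anyone else's intent.) *Anticipate* has no
lexicon entries under the 7-class DLUT ontology and is reachable only
through negated surprise.

**Labeling.** The post vector is the position-weighted sum of sentence
vectors; the label is the arg-max category, or *neutral* when the maximum is
below `δ`. Defaults: `δ = 0.5`, chosen so that a single weak emotion word
(`q = 1`) in a long post does not force a label, while any unmodified word
with `q ≥ 5` in a first/last sentence of a ≤ 4-sentence post always clears
it. Arg-max ties break on the fixed category order good, joy, surprise,
anticipate, fear, disgust, sadness, anger — determinism over semantics; ties
are measure-zero in practice. A post that is empty after cleaning is
neutral. The whole path is scale-equivariant: multiplying all intensities by
λ multiplies vectors by λ and preserves labels when δ is rescaled.

**Tokenization.** Greedy longest-match against the lexicon + modifier
vocabulary. This is deliberate: it is deterministic, dependency-free, exact
on lexicon-bearing spans, and makes fixture tests reproducible. A trained
segmenter (jieba-style) can be injected via the `tokenize` hook for real
corpora, where greedy matching may over-trigger on incidental substrings.

## Lexicon handling

Fine DLUT codes map to the seven lexical categories through an editable JSON
file (`PA,PE→joy; PD,PH,PG,PB,PK→good; NA→anger; NB,NJ,NH,PF→sadness;
NI,NC,NG→fear; ND,NE,NN,NK,NL→disgust; PC→surprise`). Polysemous entries
keep the maximum-`q` sense per (word, category) — deterministic and
conservative. Degree files may give numeric factors or one of six level
labels (most 2.0, very 1.75, more 1.5, ish 1.2, insufficiently 0.5,
over 1.5); no published factor values exist, so the table follows common
practice for Chinese degree-adverb lexicons and is fully configurable.
"Gerunds" in this context is treated as *any multiplicative modifier word*
rather than a grammatical class. Degree and negation word sets must be
disjoint. Stopwords are removed **only** on the topic-mining path: common
stopword lists contain 不, 没有, 很 — removing them before scoring would
silently delete negations and intensifiers.

## Evaluation

Standard multiclass machinery: confusion matrix (rows gold, columns
predicted), per-class precision/recall/F1, accuracy, and unweighted macro
averages. Sentiment evaluation is 3-class, emotion evaluation 9-class
(8 + neutral). Zero-denominator classes score 0 with a warning. Display
rounding is half-up to 2 decimals; full precision is kept internally. The
implementation is cross-checked against scikit-learn in the test suite but
does not depend on it for these formulas.

## Corpus aggregation

Distribution tables report per-emotion percentages at 2 d.p. and sentiment
rollups at 1 d.p. (the mixed precision convention of published tables of
this kind). The official-vs-personal comparison is a Pearson chi-square
without continuity correction on the 2×3 group-by-sentiment table;
percentages are always computed from group column sums. Daily series are
zero-filled over the corpus span; official series are conventionally scaled
by the personal/official volume ratio for plotting. Lead–lag between two
equal-length series is the shift in `[−max_lag, +max_lag]` maximizing
Pearson correlation, ties preferring the smallest |lag|; constant series
raise (correlation undefined) rather than returning an arbitrary lag.

## Topic-number selection

LDA fitting delegates to scikit-learn's batch variational implementation
with symmetric priors `α = η = 1/k` and fixed `random_state`; the
contribution here is the selection procedure, which is deterministic under a
fixed seed.

* **Perplexity elbow.** Training perplexity is recorded per `k` (whether a
  held-out perplexity was intended in the original procedure is unknowable;
  training perplexity is used and labeled as such). The upper bound
  `k_upper` is the `k` with maximal positive second-order forward difference
  of **log**-perplexity. The log scale matters: perplexity tends to decay
  geometrically in `k`, so raw second differences peak at `k = 2` on
  essentially any curve, while on the log scale a geometric decline is
  linear and the genuine turn stands out. A curve with no positive curvature
  yields the maximum `k` with a warning.
* **Coherence.** Sliding-window NPMI (window 10, step 1): word and pair
  probabilities are window occurrence fractions; NPMI is averaged over the
  top-10 word pairs of each topic, then over topics; never-co-occurring
  pairs contribute −1. `k_best` is the coherence arg-max restricted to
  `k ≤ k_upper`, ties to smaller `k`.
* **Overlap diagnostic.** The published procedure resolves near-duplicate
  topics by eye on an interactive intertopic map; this package replaces the
  visual judgment with Jensen–Shannon distance (base 2) between topic-word
  distributions, default threshold 0.25, reporting candidate pairs for a
  manual merge decision, and still emits a static PCA intertopic plot for
  inspection.

## The synthetic generator

The generator emulates the shape of a crawled Weibo export: nine raw
columns, relative posting times in three dialects (`N分钟前`, `今天 HH:MM`,
absolute), profile links in both `weibo.com/<id>` and `/u/<id>` forms,
official/personal account names, engagement counts, hashtag/mention/URL
decoration. Its defaults are the reference study conditions: the emotion
mixture of the 32,698-post corpus (38.3% good, 12.1% joy, … 25.4% neutral),
official fraction 6411/32698, a July–August 2022 span, and a one-day
official→personal lead.

Design choices that make ground truth exact rather than approximate:

* Posts are allocated to days by largest-remainder rounding of a smooth
  intensity profile (baseline + one bump peaking on an integer day); the
  personal profile is the official profile shifted by `lead_lag_days`, so
  the configured lag is present in the counts themselves, not just in
  expectation. Per-day emotion counts are allocated the same way, so corpus
  proportions match the mixture to within rounding.
* Every non-neutral post carries exactly one seeded emotion unit with
  `q ≥ 5`, placed in the first or last sentence of a ≤ 4-sentence post
  (weight ≥ 1/3), so its weighted score clears `δ = 0.5` even under the
  weakest degree factor (5 · 0.5 / 3 ≈ 0.83). Negation is seeded on an
  opposite-category word so conversion lands on the gold label; *anticipate*
  is always a negated surprise word.
* Filler vocabulary is disjoint from the lexicon and modifier lists at the
  string level, and (a tested property) produces no tokenizer hits even
  across word boundaries; neutral posts therefore cannot score. Planted-topic
  corpora use disjoint 12-word vocabularies per topic — larger than the
  10-word keyword lists, so a pure topic's keyword list is never forced to
  include out-of-block words.

What the generator does **not** emulate: natural Chinese syntax, ambiguous
or figurative emotion expression, segmentation errors, emoji/images, topic
drift, retweet cascades. Passing the recovery tests therefore demonstrates
the correctness of the scoring pipeline and aggregation arithmetic, not
field accuracy on real Weibo text — on real corpora the published benchmark
(accuracy ≈ 0.78–0.80 against hand annotation) is the realistic reference
point, and it depends on the full DLUT lexicon and a proper segmenter.

## Problem sizes and numerical choices

Tests and the acceptance script use corpora of 500–5,000 posts, planted-topic
corpora of 120 documents over 36–60 word vocabularies with `k ∈ 1…8`, and
20 seeded replicates per planted `K ∈ {3,4,5}` — sizes at which every check
runs in minutes on one CPU while leaving the statistics sharp (mixture
recovery is tested against 3 multinomial standard errors; planted-`K`
recovery within ±1 must hold in ≥ 80% of runs; measured rates at the
defaults are 100%/100%/85% for K = 3/4/5). Floating-point tolerances: weight
conservation to 1e-12; metric comparisons to printed precision with half-up
rounding; coherence uses ε = 1e-12 smoothing inside logs. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`; the
same seed reproduces corpora byte for byte.

## Known limitations

* Greedy longest-match tokenization over-triggers on incidental substrings
  in natural text; use a real segmenter there.
* The window rule attaches modifiers by proximity, not syntax; long-range
  dependencies (“不是…而是…高兴”) are mis-scored without a parser adapter.
* The lexicon shipped here is a toy for testing; field use requires the full
  DLUT ontology (not redistributable here) and ideally slang supplements.
* Lead–lag by cross-correlation is a descriptive diagnostic, not evidence of
  causal guidance between account types.
* Training perplexity decreases with `k` by construction; the elbow bound is
  a heuristic and the coherence arg-max inherits LDA's local-optimum noise
  (visible as the 85% — not 100% — recovery at K = 5).
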