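"""Generator ground truth: determinism, recovery guarantees, eval-set noise."""

import numpy as np
import pandas as pd
import pytest

from weiboemo.core import EmotionClassifier, GreedyTokenizer
from weiboemo.evaluation import evaluate_predictions
from weiboemo.lexicon import EmotionCategory, EmotionLexicon
from weiboemo.synthetic import (
    FILLER_WORDS,
    ConfigError,
    GeneratorConfig,
    allocate_largest_remainder,
    generate_corpus,
    generate_gold_eval_set,
    generate_planted_topics,
    _filler_sentence,
)


class TestConfigValidation:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            GeneratorConfig(mixture={"good": 0.5, "neutral": 0.4})

    def test_unknown_label_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            GeneratorConfig(mixture={"elation": 1.0})

    def test_rates_in_unit_interval(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(negation_rate=1.5)

    def test_lead_lag_must_fit_span(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(date_start="2022-07-01", date_end="2022-07-03", lead_lag_days=5)

    def test_anticipate_needs_surprise_words(self, lexicon, modifiers):
        no_surprise = EmotionLexicon(
            e for e in lexicon if e.category is not EmotionCategory.SURPRISE
        )
        cfg = GeneratorConfig(
            n_posts=10, mixture={"anticipate": 1.0}, official_fraction=0.0, seed=0
        )
        with pytest.raises(ConfigError, match="anticipate"):
            generate_corpus(cfg, no_surprise, modifiers)


class TestAllocation:
    def test_sums_to_total(self):
        alloc = allocate_largest_remainder(97, np.array([0.5, 0.3, 0.2]))
        assert alloc.sum() == 97

    def test_proportional_within_one(self):
        w = np.array([0.5, 0.3, 0.2])
        alloc = allocate_largest_remainder(1000, w)
        assert np.all(np.abs(alloc - 1000 * w) < 1.0)


class TestCorpusGeneration:
    def test_same_seed_byte_identical(self, lexicon, modifiers):
        cfg = GeneratorConfig(n_posts=120, seed=5)
        raw1, gold1 = generate_corpus(cfg, lexicon, modifiers)
        raw2, gold2 = generate_corpus(cfg, lexicon, modifiers)
        assert raw1.to_csv() == raw2.to_csv()
        assert gold1.to_csv() == gold2.to_csv()

    def test_different_seeds_differ(self, lexicon, modifiers):
        raw1, _ = generate_corpus(GeneratorConfig(n_posts=120, seed=5), lexicon, modifiers)
        raw2, _ = generate_corpus(GeneratorConfig(n_posts=120, seed=6), lexicon, modifiers)
        assert raw1.to_csv() != raw2.to_csv()

    def test_pure_good_mixture_exact_recovery(self, lexicon, modifiers, classifier):
        cfg = GeneratorConfig(n_posts=50, mixture={"good": 1.0}, seed=3)
        raw, gold = generate_corpus(cfg, lexicon, modifiers)
        from weiboemo.preprocess import clean_content

        labels = [classifier.annotate(clean_content(t)).label for t in raw["content"]]
        assert labels == ["good"] * 50

    def test_neutral_posts_contain_no_lexicon_words(self, lexicon, modifiers):
        cfg = GeneratorConfig(n_posts=40, mixture={"neutral": 1.0}, seed=7)
        raw, _ = generate_corpus(cfg, lexicon, modifiers)
        tok = GreedyTokenizer(lexicon.words | modifiers.words)
        for text in raw["content"]:
            hits = [t for t in tok(text) if t in lexicon.words or t in modifiers.words]
            assert hits == []

    def test_filler_vocabulary_disjoint_from_lexicon(self, lexicon, modifiers):
        tok = GreedyTokenizer(lexicon.words | modifiers.words)
        rng = np.random.default_rng(0)
        for _ in range(50):
            sentence = _filler_sentence(rng)
            assert all(
                t not in lexicon.words and t not in modifiers.words
                for t in tok(sentence)
            )
        assert not set(FILLER_WORDS) & (lexicon.words | modifiers.words)

    def test_lead_lag_shift_present_in_day_allocation(self, lexicon, modifiers):
        from weiboemo.aggregate import lead_lag

        cfg = GeneratorConfig(n_posts=800, lead_lag_days=1, seed=2)
        _, gold = generate_corpus(cfg, lexicon, modifiers)
        days = pd.to_datetime(gold["date"])
        span = pd.date_range(cfg.date_start, cfg.date_end, freq="D")
        off = days[gold["user_type"] == "official"].value_counts().reindex(span, fill_value=0)
        per = days[gold["user_type"] == "personal"].value_counts().reindex(span, fill_value=0)
        # the allocated daily profiles are maximally correlated at the
        # configured one-day shift
        assert lead_lag(off, per, max_lag=7)[0] == 1

    def test_raw_table_has_crawl_columns(self, lexicon, modifiers):
        raw, gold = generate_corpus(GeneratorConfig(n_posts=30, seed=1), lexicon, modifiers)
        expected = {
            "publisher",
            "content",
            "publisher_link",
            "posting_time",
            "source",
            "comments",
            "retweets",
            "likes",
            "current_time",
        }
        assert expected <= set(raw.columns)
        assert len(raw) == len(gold) == 30


class TestGoldEvalSet:
    def test_no_noise_perfect_metrics(self):
        df = generate_gold_eval_set(200, ["a", "b", "c"], noise=0.0, seed=0)
        rep = evaluate_predictions(df["gold"], df["predicted"], ["a", "b", "c"])
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0

    def test_symmetric_noise_accuracy_near_closed_form(self):
        df = generate_gold_eval_set(4000, ["a", "b", "c"], noise=0.10, seed=1)
        rep = evaluate_predictions(df["gold"], df["predicted"], ["a", "b", "c"])
        # binomial sampling error around 0.90 at n=4000: 3 sigma ~ 0.014
        assert rep.accuracy == pytest.approx(0.90, abs=0.02)

    def test_never_predicted_class_exercises_warning_path(self):
        df = generate_gold_eval_set(60, ["a", "b"], noise=0.0, seed=2)
        df.loc[df["predicted"] == "b", "predicted"] = "a"
        with pytest.warns(UserWarning, match="never predicted"):
            rep = evaluate_predictions(df["gold"], df["predicted"], ["a", "b"])
        assert rep.recall["b"] == 0.0

    def test_noise_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            generate_gold_eval_set(10, ["a", "b"], noise=1.2)


class TestPlantedTopics:
    def test_documents_single_block(self):
        docs, topics = generate_planted_topics(3, n_docs=30, seed=0)
        for doc, k in zip(docs, topics):
            assert {w.split("w")[0] for w in doc} == {f"t{k}"}

    def test_deterministic(self):
        assert generate_planted_topics(3, seed=5) == generate_planted_topics(3, seed=5)
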