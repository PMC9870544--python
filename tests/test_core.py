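"""Sentence weighting, emotion-unit scoring, conversion, post classification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weiboemo.core import (
    EmotionClassifier,
    EmotionUnit,
    classify_post,
    convert_bidirectional,
    extract_units,
    post_vector,
    score_unit,
    sentence_vector,
    sentence_weights,
    split_sentences,
)
from weiboemo.lexicon import CATEGORIES, EmotionCategory

JOY = EmotionCategory.JOY
GOOD = EmotionCategory.GOOD
FEAR = EmotionCategory.FEAR


class TestSentenceWeights:
    def test_four_sentences(self):
        assert np.allclose(sentence_weights(4), [1 / 3, 1 / 6, 1 / 6, 1 / 3])

    @pytest.mark.parametrize("n, expected", [(1, [1.0]), (2, [0.5, 0.5])])
    def test_short_posts_uniform(self, n, expected):
        assert np.allclose(sentence_weights(n), expected)

    @pytest.mark.parametrize("n", range(1, 51))
    def test_conservation_and_endpoints(self, n):
        w = sentence_weights(n)
        assert abs(w.sum() - 1.0) < 1e-12
        if n > 2:
            assert w[0] == w[-1] == 2 / (n + 2)
            assert np.allclose(w[1:-1], 1 / (n + 2))


class TestSplitSentences:
    def test_mixed_separators_with_trailing_segment(self):
        spans = split_sentences("A。B！C？D")
        assert [s.text for s in spans] == ["A", "B", "C", "D"]
        assert np.allclose([s.weight for s in spans], [1 / 3, 1 / 6, 1 / 6, 1 / 3])

    def test_single_unterminated(self):
        (span,) = split_sentences("A")
        assert span.text == "A" and span.weight == 1.0

    def test_two_terminated(self):
        spans = split_sentences("A。B。")
        assert [s.weight for s in spans] == [0.5, 0.5]

    def test_empty_segments_dropped(self):
        assert len(split_sentences("。。A。！")) == 1

    def test_empty_text(self):
        assert split_sentences("") == []


class TestScoreUnit:
    @pytest.mark.parametrize(
        "q, m, factors, expected",
        [
            (5, 0, (), 5.0),
            (5, 1, (1.75,), -8.75),
            (7, 2, (2.0, 0.5), 7.0),
        ],
    )
    def test_examples(self, q, m, factors, expected):
        unit = EmotionUnit("w", JOY, q, m, factors)
        assert score_unit(unit) == pytest.approx(expected)

    def test_brute_force_oracle(self):
        # exhaustive: q in odd 1..9, m <= 3, up to 2 factors from the default table
        table = [2.0, 1.75, 1.5, 1.2, 0.5]
        factor_sets = [()] + [(a,) for a in table] + list(
            itertools.product(table, repeat=2)
        )
        cases = 0
        for q in (1, 3, 5, 7, 9):
            for m in range(4):
                for factors in factor_sets:
                    expected = q
                    for c in factors:  # independent product accumulation
                        expected = expected * c
                    if m % 2 == 1:
                        expected = -expected
                    got = score_unit(EmotionUnit("w", JOY, q, m, factors))
                    assert got == pytest.approx(expected)
                    cases += 1
        assert cases >= 500

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            score_unit(EmotionUnit("w", JOY, 0, 0, ()))
        with pytest.raises(ValueError):
            score_unit(EmotionUnit("w", JOY, 5, 0, (-1.0,)))


class TestConvertBidirectional:
    @pytest.mark.parametrize(
        "cat, score, expected",
        [
            (EmotionCategory.SURPRISE, -3, (EmotionCategory.ANTICIPATE, 3)),
            (EmotionCategory.JOY, -2, (EmotionCategory.SADNESS, 2)),
            (GOOD, 5, (GOOD, 5)),
            (GOOD, 0, (GOOD, 0)),
        ],
    )
    def test_examples(self, cat, score, expected):
        assert convert_bidirectional(cat, score) == expected

    @pytest.mark.parametrize("cat", CATEGORIES)
    def test_exhaustive_pairs(self, cat):
        assert convert_bidirectional(cat, -1.0) == (cat.opposite(), 1.0)
        assert convert_bidirectional(cat, 1.0) == (cat, 1.0)

    @pytest.mark.parametrize("cat", CATEGORIES)
    def test_double_flip_returns_original(self, cat):
        flipped, s = convert_bidirectional(cat, -2.0)
        back, s2 = convert_bidirectional(flipped, -s)
        assert back is cat and s2 == 2.0


class TestVectors:
    def test_sentence_vector_converts_then_sums(self):
        units = [
            EmotionUnit("a", JOY, 5, 0, ()),
            EmotionUnit("b", JOY, 2, 1, ()),  # negated joy -> sadness 2
        ]
        v = sentence_vector(units)
        assert v[JOY.index] == 5
        assert v[EmotionCategory.SADNESS.index] == 2
        assert v.sum() == 7

    def test_no_units_zero_vector(self):
        assert not sentence_vector([]).any()

    def test_additivity_same_category(self):
        units = [EmotionUnit("a", GOOD, 3), EmotionUnit("b", GOOD, 4)]
        assert sentence_vector(units)[GOOD.index] == 7

    def test_post_vector_weighted_sum(self):
        spans = split_sentences("A。B。C。")
        e = np.zeros(8)
        e[FEAR.index] = 5
        vec = post_vector([(spans[0], np.zeros(8)), (spans[1], np.zeros(8)), (spans[2], e)])
        assert vec[FEAR.index] == pytest.approx(0.4 * 5)  # w3 = 2/(3+2)

    def test_post_vector_two_even_sentences(self):
        spans = split_sentences("A。B。")
        e1, e2 = np.zeros(8), np.zeros(8)
        e1[GOOD.index], e2[GOOD.index] = 4, 2
        assert post_vector([(spans[0], e1), (spans[1], e2)])[GOOD.index] == 3


class TestClassifyPost:
    def test_zero_vector_neutral(self):
        assert classify_post(np.zeros(8), 0.5) == ("neutral", "neutral")

    def test_above_threshold(self):
        v = np.zeros(8)
        v[GOOD.index] = 3.2
        assert classify_post(v, 0.5) == ("good", "positive")

    def test_below_threshold(self):
        v = np.zeros(8)
        v[GOOD.index] = 0.3
        assert classify_post(v, 0.5) == ("neutral", "neutral")

    def test_tie_breaks_on_fixed_category_order(self):
        v = np.zeros(8)
        v[EmotionCategory.SADNESS.index] = 2.0
        v[EmotionCategory.SURPRISE.index] = 2.0
        assert classify_post(v, 0.5)[0] == "surprise"

    def test_delta_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_post(np.zeros(8), 0.0)


class TestExtractUnits:
    def test_degree_adverb_window(self, lexicon, modifiers):
        (unit,) = extract_units("非常高兴", lexicon, modifiers)
        assert unit.category is JOY and unit.negation_count == 0
        assert unit.factors == (1.75,)

    def test_negation_window(self, lexicon, modifiers):
        (unit,) = extract_units("不高兴", lexicon, modifiers)
        assert unit.negation_count == 1 and unit.factors == ()

    def test_no_lexicon_hits(self, lexicon, modifiers):
        assert extract_units("天气晴朗", lexicon, modifiers) == []

    def test_window_does_not_cross_comma(self, lexicon, modifiers):
        (unit,) = extract_units("不，高兴", lexicon, modifiers)
        assert unit.negation_count == 0

    def test_window_limited_to_three_tokens(self, lexicon, modifiers):
        # negation sits four filler tokens before the emotion word
        (unit,) = extract_units("不天气晴朗高兴", lexicon, modifiers)
        assert unit.negation_count == 0

    def test_parser_adapter_attachment(self, lexicon, modifiers):
        parser = lambda text: [("高兴", ["不", "很"])]
        (unit,) = extract_units("x", lexicon, modifiers, parser)
        assert unit.negation_count == 1 and unit.factors == (1.75,)

    def test_failing_parser_falls_back_to_window(self, lexicon, modifiers, caplog):
        def parser(text):
            raise RuntimeError("parser crash")

        with caplog.at_level("WARNING"):
            (unit,) = extract_units("不高兴", lexicon, modifiers, parser)
        assert unit.negation_count == 1
        assert any("fallback" in r.message for r in caplog.records)


class TestClassifier:
    def test_empty_post_is_neutral(self, classifier):
        assert classifier.annotate("").label == "neutral"

    def test_deterministic(self, classifier):
        text = "非常高兴！但是也有点担心。"
        a, b = classifier.annotate(text), classifier.annotate(text)
        assert a.label == b.label
        assert np.array_equal(a.vector, b.vector)

    def test_scale_equivariance(self, lexicon, modifiers):
        lam = 3.0
        base = EmotionClassifier(lexicon=lexicon, modifiers=modifiers, delta=0.5)
        scaled = EmotionClassifier(
            lexicon=lexicon.scaled(lam), modifiers=modifiers, delta=0.5 * lam
        )
        for text in ["非常高兴！", "不高兴。担心。", "天气晴朗。", "很讨厌！路上风景。加油！"]:
            a, b = base.annotate(text), scaled.annotate(text)
            assert np.allclose(b.vector, lam * a.vector)
            assert a.label == b.label

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, derandomize=True)
    def test_label_always_valid(self, classifier, seed):
        rng = np.random.default_rng(seed)
        frags = ["高兴", "不", "很", "担心", "天气", "。", "！", "，", "#x#"]
        text = "".join(rng.choice(frags, size=rng.integers(0, 12)))
        result = classifier.annotate(text)
        valid = {c.value for c in CATEGORIES} | {"neutral"}
        assert result.label in valid
        assert (result.vector >= 0).all()
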