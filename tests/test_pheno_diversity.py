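"""Shannon indices, 1-10 quantitative scoring and population comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from germdiv import (
    ScoringScheme,
    category_frequencies,
    compare_populations,
    qualitative_trait_summary,
    quantitative_trait_summary,
    scheme_from_values,
    score_quantitative,
    shannon_index,
)
from germdiv.pheno_diversity import DegenerateTraitError, EmptyTraitError


class TestCategoryFrequencies:
    def test_panel_counts(self):
        # 94 accessions split 16/72/6 -> the published plant-habit frequencies
        values = [1] * 16 + [2] * 72 + [3] * 6
        freqs = category_frequencies(values)
        assert np.allclose(freqs.to_numpy(), [0.170, 0.766, 0.064], atol=5e-4)

    def test_uniform_and_constant(self):
        assert category_frequencies([1, 1, 2, 2]).tolist() == [0.5, 0.5]
        assert category_frequencies([7, 7]).tolist() == [1.0]

    def test_all_missing_raises(self):
        with pytest.raises(EmptyTraitError):
            category_frequencies([np.nan, np.nan])


class TestShannonIndex:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            # published worked rows: plant habit LLR/CBL, fruit glossiness LLR
            ([0.170, 0.766, 0.064], 0.68),
            ([0.118, 0.788, 0.094], 0.66),
            ([0.053, 0.947], 0.21),
            ([1.0], 0.00),
            ([0.5, 0.5], 0.69),
        ],
    )
    def test_worked_examples_2dp(self, freqs, expected):
        assert round(shannon_index(freqs), 2) == pytest.approx(expected)

    def test_uniform_closed_form(self):
        assert shannon_index([0.5, 0.5]) == pytest.approx(np.log(2))

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([1.2, -0.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(1, 50), min_size=1, max_size=8))
    def test_bounds_and_merge_property(self, counts):
        """0 <= H' <= ln k, and merging two categories never increases H'."""
        p = np.array(counts, dtype=float)
        p /= p.sum()
        h = shannon_index(p)
        assert -1e-12 <= h <= np.log(len(p)) + 1e-12
        if len(p) >= 2:
            merged = np.concatenate([[p[0] + p[1]], p[2:]])
            assert shannon_index(merged) <= h + 1e-12


class TestScoring:
    SCHEME = ScoringScheme(M=100.0, S=10.0)

    @pytest.mark.parametrize(
        "x, score",
        [
            (100.0, 6),    # x == M sits on the 5/6 edge; left-closed bins
            (70.0, 1),     # M - 3S
            (120.0, 10),   # boundary M + 2S -> 10 ("greater than or equal")
            (79.999, 1),
            (80.0, 2),     # M - 2S is the first interior edge
            (119.999, 9),
        ],
    )
    def test_edge_cases(self, x, score):
        assert score_quantitative([x], self.SCHEME).iloc[0] == score

    def test_degenerate_sd_rejected(self):
        with pytest.raises(DegenerateTraitError):
            score_quantitative([1.0], ScoringScheme(M=1.0, S=0.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m=st.floats(-50, 50),
        s=st.floats(0.1, 20),
        xs=st.lists(st.floats(-500, 500), min_size=2, max_size=30),
    )
    def test_partition_and_monotone(self, m, s, xs):
        """Every value maps to exactly one score in 1..10; scoring is monotone."""
        scheme = ScoringScheme(M=m, S=s)
        scores = score_quantitative(xs, scheme)
        assert scores.between(1, 10).all()
        order = np.argsort(xs, kind="stable")
        assert (np.diff(scores.to_numpy(dtype=float)[order]) >= 0).all()

    def test_score_histogram_matches_normal_bins(self):
        """On N(M, S^2) draws the empirical score distribution matches the
        normal-CDF bin probabilities within binomial error."""
        rng = np.random.default_rng(7)
        scheme = ScoringScheme(M=50.0, S=5.0)
        n = 1000
        x = rng.normal(scheme.M, scheme.S, size=n)
        scores = score_quantitative(x, scheme)
        edges = np.concatenate([[-np.inf], scheme.edges, [np.inf]])
        probs = np.diff(stats.norm.cdf(edges, loc=scheme.M, scale=scheme.S))
        for k in range(1, 11):
            observed = (scores == k).mean()
            se = np.sqrt(probs[k - 1] * (1 - probs[k - 1]) / n)
            assert abs(observed - probs[k - 1]) < 4 * se + 1e-9


class TestQuantitativeSummary:
    def test_published_cv_and_range(self):
        # CBL plant height: mean 102.0, SD 16.6 -> CV 16.3%; LLR range 130.0
        assert 16.6 / 102.0 * 100 == pytest.approx(16.3, abs=0.05)
        x = [1.0, 2.0, 3.0]
        s = quantitative_trait_summary("t", x, ScoringScheme(M=2.0, S=1.0))
        assert s.stats["Mean"] == 2.0
        assert s.stats["SD"] == pytest.approx(1.0)
        assert s.stats["CV"] == pytest.approx(50.0)
        assert s.stats["Range"] == s.stats["Max"] - s.stats["Min"]

    def test_shannon_from_scores_not_raw(self):
        x = np.linspace(0, 100, 50)
        scheme = scheme_from_values(x)
        s = quantitative_trait_summary("t", x, scheme)
        assert s.frequencies.sum() == pytest.approx(1.0)
        assert set(s.frequencies.index) <= set(range(1, 11))

    def test_zero_mean_cv_undefined(self):
        with pytest.raises(DegenerateTraitError):
            quantitative_trait_summary("t", [-1.0, 1.0], ScoringScheme(M=0.0, S=1.0))


class TestComparePopulations:
    def test_shannon_difference(self):
        a = qualitative_trait_summary("habit", [1] * 16 + [2] * 72 + [3] * 6)
        b = qualitative_trait_summary("habit", [1] * 10 + [2] * 67 + [3] * 8)
        d = compare_populations(a, b)
        assert round(d["shannon_diff"], 2) == pytest.approx(0.02)

    def test_identical_populations_zero(self):
        a = qualitative_trait_summary("t", [1, 1, 2, 3])
        d = compare_populations(a, a)
        assert d["shannon_diff"] == 0.0
        assert (d["frequency_diff"] == 0).all()

    def test_constructed_shift_recovered(self):
        a = qualitative_trait_summary("t", [1] * 60 + [2] * 40)
        b = qualitative_trait_summary("t", [1] * 50 + [2] * 50)
        d = compare_populations(a, b)
        assert d["frequency_diff"][1] == pytest.approx(0.1)
        assert d["frequency_diff"][2] == pytest.approx(-0.1)

    def test_mismatched_traits_rejected(self):
        a = qualitative_trait_summary("t1", [1, 2])
        b = qualitative_trait_summary("t2", [1, 2])
        with pytest.raises(ValueError):
            compare_populations(a, b)
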