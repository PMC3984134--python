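"""Normalisation, detection limits, gamma correlation, bootstrap, residuals."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symdeep.mapping import TypeAnnotation
from symdeep.quantify import (
    AbundanceTable,
    DetectionLimit,
    UndefinedGamma,
    bootstrap_ci,
    detection_cutoff,
    estimate_detection_limit,
    gamma_correlation,
    gamma_permutation_p,
    normalize_and_aggregate,
    residual_bias,
)


def brute_force_gamma(x, y, r=0.0):
    """Independent oracle: explicit enumeration of all index pairs."""
    nc = nd = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if abs(dx) > r and abs(dy) > r:
            if (dx > 0) == (dy > 0):
                nc += 1
            else:
                nd += 1
    if nc + nd == 0:
        return None
    return (nc - nd) / (nc + nd), nc, nd


def _annotations(mapping):
    return [TypeAnnotation(ref, t, 100.0) for ref, t in mapping.items()]


class TestNormalizeAggregate:
    def test_even_split(self):
        counts = pd.DataFrame({"refA": {"s1": 50}, "refB": {"s1": 50}})
        table = normalize_and_aggregate(
            counts, _annotations({"refA": "X", "refB": "Y"})
        )
        assert table.reference_percents.loc["s1", "refA"] == pytest.approx(50.0)
        assert table.reference_percents.loc["s1", "refB"] == pytest.approx(50.0)

    def test_type_percents_sum_member_references(self):
        counts = pd.DataFrame({"a": {"s1": 2}, "b": {"s1": 3}, "c": {"s1": 5}})
        table = normalize_and_aggregate(
            counts, _annotations({"a": "X", "b": "X", "c": "Y"})
        )
        assert table.type_percents.loc["s1", "X"] == pytest.approx(50.0)
        assert table.type_percents.loc["s1", "Y"] == pytest.approx(50.0)

    def test_type_percents_sum_to_100(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(6, 5)),
            index=[f"s{i}" for i in range(6)],
            columns=list("abcde"),
        )
        table = normalize_and_aggregate(
            counts, _annotations({"a": "X", "b": "X", "c": "Y", "d": "Z", "e": "Z"})
        )
        assert table.type_percents.sum(axis=1).to_numpy() == pytest.approx(
            [100.0] * 6
        )

    def test_zero_mapped_sample_flagged(self):
        counts = pd.DataFrame({"a": {"s1": 10, "s2": 0}, "b": {"s1": 10, "s2": 0}})
        table = normalize_and_aggregate(counts, _annotations({"a": "X", "b": "X"}))
        assert table.zero_mapped_samples == ["s2"]
        assert np.isnan(table.reference_percents.loc["s2", "a"])

    def test_unannotated_reference_rejected(self):
        counts = pd.DataFrame({"a": {"s1": 10}})
        with pytest.raises(KeyError):
            normalize_and_aggregate(counts, [])


class TestDetectionLimit:
    def test_printed_mean_and_se_give_011_cutoff(self):
        assert detection_cutoff(0.07, 0.02) == pytest.approx(0.11)

    def test_all_zero_false_positives_give_zero_cutoff(self):
        limit = DetectionLimit(fp_values=[0.0, 0.0, 0.0])
        assert limit.cutoff == 0.0

    def test_hand_computed_se(self):
        values = [0.05, 0.07, 0.09]
        limit = DetectionLimit(fp_values=values)
        sd = np.std(values, ddof=1)
        assert limit.mean_fp == pytest.approx(0.07)
        assert limit.se_fp == pytest.approx(sd / np.sqrt(3))
        assert limit.cutoff == pytest.approx(0.07 + 2 * sd / np.sqrt(3))

    def test_outlier_excluded_then_stats_recomputed(self):
        counts = pd.DataFrame(
            {
                "a": {"p1": 10_000, "p2": 10_000, "p3": 8440},
                "b": {"p1": 5, "p2": 7, "p3": 1560},
            }
        )
        table = normalize_and_aggregate(counts, _annotations({"a": "X", "b": "Y"}))
        designs = {
            "p1": {"X": 1.0, "Y": 0.0},
            "p2": {"X": 1.0, "Y": 0.0},
            "p3": {"X": 1.0, "Y": 0.0},
        }
        limit = estimate_detection_limit(table, designs, outlier_k=5)
        assert len(limit.outliers) == 1
        assert limit.outliers[0] == pytest.approx(15.6)
        assert limit.mean_fp < 0.1

    def test_no_absent_types_fails(self):
        counts = pd.DataFrame({"a": {"s1": 10}})
        table = normalize_and_aggregate(counts, _annotations({"a": "X"}))
        with pytest.raises(ValueError):
            estimate_detection_limit(table, {"s1": {"X": 1.0}})


class TestGamma:
    def test_monotone_data(self):
        x = [1, 2, 3, 4, 5]
        assert gamma_correlation(x, [2, 4, 6, 8, 10]).gamma == 1.0
        assert gamma_correlation(x, [10, 8, 6, 4, 2]).gamma == -1.0

    def test_hand_enumerated_example(self):
        result = gamma_correlation([1, 2, 2, 3, 4], [1, 3, 2, 1, 5])
        assert result.n_concordant == 6
        assert result.n_discordant == 2
        assert result.gamma == pytest.approx(0.5)

    def test_all_ties_undefined(self):
        with pytest.raises(UndefinedGamma):
            gamma_correlation([1, 1, 1], [2, 3, 4])

    def test_tolerance_converts_small_differences_to_ties(self):
        x = [0.0, 0.05, 1.0]
        y = [0.0, -0.05, 1.0]
        assert gamma_correlation(x, y, tolerance_r=0.0).gamma < 1.0
        assert gamma_correlation(x, y, tolerance_r=0.1).gamma == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=-50, max_value=50),
                st.integers(min_value=-50, max_value=50),
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_matches_brute_force_enumeration(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        oracle = brute_force_gamma(x, y)
        if oracle is None:
            with pytest.raises(UndefinedGamma):
                gamma_correlation(x, y)
        else:
            result = gamma_correlation(x, y)
            assert result.gamma == pytest.approx(oracle[0])
            assert (result.n_concordant, result.n_discordant) == oracle[1:]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=-20, max_value=20),
                st.integers(min_value=-20, max_value=20),
            ),
            min_size=3,
            max_size=10,
        )
    )
    def test_antisymmetric_in_y(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        try:
            forward = gamma_correlation(x, y).gamma
        except UndefinedGamma:
            return
        backward = gamma_correlation(x, [-v for v in y]).gamma
        assert backward == pytest.approx(-forward)


class TestGammaPermutation:
    def test_monotone_association_significant(self):
        x = list(range(8))
        y = [v * 2 + 1 for v in x]
        result = gamma_permutation_p(x, y, n_iter=1000, seed=0)
        assert result.gamma == 1.0
        assert result.p_value <= 0.01

    def test_constant_x_undefined(self):
        with pytest.raises(UndefinedGamma):
            gamma_permutation_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_deterministic_per_seed(self):
        x = [1, 4, 2, 8, 5, 7]
        y = [2, 3, 1, 9, 4, 8]
        a = gamma_permutation_p(x, y, n_iter=500, seed=7)
        b = gamma_permutation_p(x, y, n_iter=500, seed=7)
        assert a.p_value == b.p_value


class TestBootstrap:
    def test_constant_values_degenerate_interval(self):
        ci = bootstrap_ci([3.5] * 10, seed=1)
        assert ci.lower == ci.mean == ci.upper == 3.5

    def test_deterministic_per_seed(self):
        values = [1.0, 5.0, 2.0, 8.0, 3.0]
        a = bootstrap_ci(values, seed=3)
        b = bootstrap_ci(values, seed=3)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_coverage_of_true_mean(self):
        # 95 % percentile intervals should cover the true mean in roughly
        # 95 % of repetitions (binomial slack at 200 reps)
        rng = np.random.default_rng(12)
        true_mean = 10.0
        covered = 0
        reps = 200
        for i in range(reps):
            sample = rng.normal(true_mean, 3.0, size=40)
            ci = bootstrap_ci(sample, n_resamples=400, seed=i)
            covered += ci.lower <= true_mean <= ci.upper
        assert 0.88 <= covered / reps <= 1.0


class TestResidualBias:
    def test_perfect_fit_zero_residuals(self):
        expected = [0.1, 1.0, 5.0, 0.1, 1.0, 5.0]
        summary = residual_bias(expected, expected)
        assert summary.residuals == pytest.approx([0.0] * 6)

    def test_constant_shift_absorbed_by_intercept(self):
        expected = np.array([0.1, 1.0, 5.0, 0.1, 1.0, 5.0])
        summary = residual_bias(expected + 1.0, expected)
        assert summary.residuals == pytest.approx([0.0] * 6, abs=1e-12)
        assert summary.intercept == pytest.approx(1.0)

    def test_known_inflation_counted_as_overestimate(self):
        expected = np.array([0.1, 0.1, 1.0, 1.0, 5.0, 5.0])
        observed = expected.copy()
        observed[:2] += 2.0  # inflate the 0.1 % level
        summary = residual_bias(observed, expected)
        level = summary.per_level.set_index("expected")
        assert level.loc[0.1, "overestimated"] == 2
        assert level.loc[0.1, "underestimated"] == 0

    def test_degenerate_expected_rejected(self):
        with pytest.raises(ValueError):
            residual_bias([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
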