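"""Correlation reporting, reliability, attenuation and comparison tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexnorm.evaluation import (
    compare_dependent_correlations,
    compare_independent_correlations,
    disattenuate,
    fisher_ci,
    pearson_with_ci,
    residual_incremental_r2,
    round_half_up,
    spearman_brown,
    split_half_reliability,
)


class TestPearsonWithCI:
    def test_fisher_interval_formula(self):
        # hand oracle: r = 0.8 for x=(1,2,3,4), y=(1,3,2,4);
        # CI = tanh(atanh(r) +/- 1.96/sqrt(n-3)) with n = 4
        rep = pearson_with_ci([1, 2, 3, 4], [1, 3, 2, 4])
        assert rep.r == pytest.approx(0.8)
        assert rep.ci_low == pytest.approx(math.tanh(math.atanh(0.8) - 1.959963984540054))
        assert rep.ci_high == pytest.approx(math.tanh(math.atanh(0.8) + 1.959963984540054))

    def test_large_sample_interval_at_two_decimals(self):
        rep = fisher_ci(0.87, 2831)
        assert (round_half_up(rep.ci_low), round_half_up(rep.ci_high)) == (0.86, 0.88)

    def test_perfectly_linear_degenerate_interval(self):
        x = np.arange(10.0)
        rep = pearson_with_ci(x, 2 * x + 1)
        assert rep.r == 1.0 and (rep.ci_low, rep.ci_high) == (1.0, 1.0)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 2, 3], [3, 2, 1])

    @given(
        seed=st.integers(0, 1000),
        slope=st.floats(0.1, 5),
        offset=st.floats(-10, 10),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_and_positive_affine_invariance(self, seed, slope, offset):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = pearson_with_ci(x, y)
        b = pearson_with_ci(y, x)
        c = pearson_with_ci(slope * x + offset, y)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.r == pytest.approx(c.r, rel=1e-9)
        assert (a.ci_low, a.ci_high) == pytest.approx((b.ci_low, b.ci_high))


class TestSpearmanBrown:
    @pytest.mark.parametrize(
        "r_half,expected", [(0.5, 2 / 3), (1.0, 1.0), (0.0, 0.0)]
    )
    def test_known_values(self, r_half, expected):
        assert spearman_brown(r_half) == pytest.approx(expected)

    def test_minus_one_errors(self):
        with pytest.raises(ValueError):
            spearman_brown(-1.0)


class TestSplitHalfReliability:
    def test_identical_raters_give_one(self):
        words = np.linspace(1, 7, 20)
        mat = np.tile(words, (6, 1))
        for seed in (0, 7):
            rep = split_half_reliability(mat, 50, seed=seed)
            assert rep.reliability == pytest.approx(1.0)

    def test_pure_noise_raters_near_zero(self):
        # two independent-noise raters share no true signal, so the
        # split-half correlation is sampling noise around zero
        rng = np.random.default_rng(4)
        mat = rng.normal(4, 1, (2, 2000))
        rep = split_half_reliability(mat, 1000, seed=0)
        assert abs(rep.reliability) < 0.1

    def test_recovers_parallel_measurement_reliability(self):
        # true scores with variance st2, P raters with noise variance se2:
        # reliability of the mean rating = st2 / (st2 + se2 / P)
        rng = np.random.default_rng(12)
        n_words, n_raters = 500, 12
        st2, se2 = 1.3, 0.8
        true = rng.normal(0, math.sqrt(st2), n_words)
        mat = true[None, :] + rng.normal(0, math.sqrt(se2), (n_raters, n_words))
        rep = split_half_reliability(mat, 500, seed=1)
        expected = st2 / (st2 + se2 / n_raters)
        assert rep.reliability == pytest.approx(expected, abs=0.03)

    def test_fixed_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(4, 1, (8, 30)) + rng.normal(0, 1, 30)[None, :]
        a = split_half_reliability(mat, 200, seed=42)
        b = split_half_reliability(mat, 200, seed=42)
        assert a.reliability == b.reliability

    def test_all_missing_half_drops_word(self, caplog):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 30)
        mat = base[None, :] + rng.normal(0, 0.1, (4, 30))
        mat[:, 0] = np.nan  # this word can never be scored
        with caplog.at_level("INFO"):
            rep = split_half_reliability(mat, 20, seed=0)
        assert -1 <= rep.reliability <= 1

    def test_odd_rater_count_splits_unevenly(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 40)
        mat = base[None, :] + rng.normal(0, 0.3, (5, 40))
        rep = split_half_reliability(mat, 100, seed=3)
        assert 0.5 < rep.reliability <= 1.0


class TestDisattenuate:
    @pytest.mark.parametrize(
        "r,rel,expected",
        [(0.84, 0.97, 0.85), (0.59, 0.92, 0.62)],
    )
    def test_published_style_examples(self, r, rel, expected):
        assert round_half_up(disattenuate(r, rel, 1.0)) == expected

    def test_unit_reliabilities_are_identity(self):
        assert disattenuate(0.73, 1.0, 1.0) == pytest.approx(0.73)

    def test_clipped_at_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert disattenuate(0.99, 0.5, 0.5) == 1.0
        assert any("clipped" in m for m in caplog.messages)

    def test_nonpositive_reliability_errors(self):
        with pytest.raises(ValueError):
            disattenuate(0.5, 0.0, 1.0)

    @given(
        r=st.floats(0.05, 0.9),
        rel_a=st.floats(0.5, 1.0),
        rel_b=st.floats(0.5, 1.0),
        bump=st.floats(0.01, 0.1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_r_and_antitone_in_reliability(self, r, rel_a, rel_b, bump):
        base = disattenuate(r, rel_a, rel_b)
        assert disattenuate(min(r + bump, 1.0), rel_a, rel_b) >= base
        assert disattenuate(r, min(rel_a + bump, 1.0), rel_b) <= base


class TestResidualIncrementalR2:
    def test_identical_predictors_give_zero(self):
        rng = np.random.default_rng(0)
        human = rng.normal(4, 1, 50)
        pred = human + rng.normal(0, 0.5, 50)
        assert residual_incremental_r2(human, pred, pred) == pytest.approx(0.0, abs=1e-12)

    def test_unrelated_predictor_near_zero(self):
        rng = np.random.default_rng(1)
        human = rng.normal(4, 1, 2000)
        pred = human + rng.normal(0, 0.5, 2000)
        other = rng.normal(0, 1, 2000)
        assert residual_incremental_r2(human, pred, other) < 0.01

    def test_six_point_hand_ols_oracle(self):
        # oracle: solve both regressions from the normal equations directly
        human = np.array([1.0, 2.0, 2.5, 4.0, 5.5, 6.0])
        a = np.array([1.2, 1.8, 3.0, 3.8, 5.0, 6.2])
        b = np.array([0.5, 2.5, 2.0, 4.5, 4.8, 6.5])

        def ols_fit(y, x):
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            return y - X @ beta

        resid = ols_fit(human, a)
        resid2 = ols_fit(resid, b)
        r2_oracle = 1 - resid2 @ resid2 / ((resid - resid.mean()) @ (resid - resid.mean()))
        assert residual_incremental_r2(human, a, b) == pytest.approx(r2_oracle, abs=1e-9)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            residual_incremental_r2([1, 2, 3, 4], [1, 1, 1, 1], [1, 2, 3, 4])

    @given(seed=st.integers(0, 300))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_total_explained_variance_bounded(self, seed):
        rng = np.random.default_rng(seed)
        human = rng.normal(0, 1, 40)
        a = human + rng.normal(0, 1, 40)
        b = human + rng.normal(0, 1, 40)
        r2_a = np.corrcoef(human, a)[0, 1] ** 2
        assert residual_incremental_r2(human, a, b) + r2_a <= 1 + 1e-9


class TestIndependentComparison:
    def test_equal_correlations_give_p_one(self):
        rep = compare_independent_correlations(0.5, 100, 0.5, 100)
        assert rep.statistics["fisher_z"] == pytest.approx(0.0)
        assert rep.p == pytest.approx(1.0)

    def test_large_separated_samples_significant(self):
        rep = compare_independent_correlations(0.92, 946, 0.71, 951)
        assert rep.p < 0.001

    def test_hand_formula_example(self):
        rep = compare_independent_correlations(0.5, 100, 0.3, 100)
        assert rep.statistics["fisher_z"] == pytest.approx(1.6699, abs=1e-4)
        assert rep.p == pytest.approx(0.0949, abs=1e-3)

    def test_unit_correlation_errors(self):
        with pytest.raises(ValueError):
            compare_independent_correlations(1.0, 100, 0.5, 100)


def _dependent_oracles(a, b, c, n):
    """Independent textbook evaluations of the three dependent-correlation z's.

    a = r(h, y1), b = r(h, y2), c = r(y1, y2); written without reference to
    the implementation (plain formula transcription).
    """
    za, zb = math.atanh(a), math.atanh(b)
    out = {}
    # Steiger 1980, using the mean of the two correlations
    rm = (a + b) / 2
    cov = (c * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - c**2)) / (1 - rm**2) ** 2
    out["steiger"] = (za - zb) * math.sqrt(n - 3) / math.sqrt(2 - 2 * cov)
    # Hittner, May & Silver 2003: same form, mean taken on the Fisher-z scale
    rz = math.tanh((za + zb) / 2)
    cov = (c * (1 - 2 * rz**2) - 0.5 * rz**2 * (1 - 2 * rz**2 - c**2)) / (1 - rz**2) ** 2
    out["hittner_may_silver"] = (za - zb) * math.sqrt(n - 3) / math.sqrt(2 - 2 * cov)
    # Meng, Rosenthal & Rubin 1992
    r2 = (a**2 + b**2) / 2
    f = min((1 - c) / (2 * (1 - r2)), 1.0)
    h = (1 - f * r2) / (1 - r2)
    out["meng_rosenthal_rubin"] = (za - zb) * math.sqrt((n - 3) / (2 * (1 - c) * h))
    return out


class TestDependentComparison:
    def test_equal_correlations_give_p_one(self):
        rep = compare_dependent_correlations(0.6, 0.6, 0.4, 100)
        assert all(z == pytest.approx(0.0) for z in rep.statistics.values())
        assert rep.p == pytest.approx(1.0)

    @pytest.mark.parametrize("r12", [0.5, 0.7, 0.9])
    def test_large_sample_difference_significant(self, r12):
        rep = compare_dependent_correlations(0.91, 0.78, r12, 2831)
        assert rep.p < 0.001
        assert rep.difference == pytest.approx(0.13)

    def test_matches_textbook_formulas(self):
        rep = compare_dependent_correlations(0.6, 0.4, 0.3, 50)
        oracle = _dependent_oracles(0.6, 0.4, 0.3, 50)
        for method, z in oracle.items():
            assert rep.statistics[method] == pytest.approx(z, abs=1e-6)

    def test_conservative_p_is_the_maximum(self):
        rep = compare_dependent_correlations(0.7, 0.5, 0.6, 80)
        assert rep.p == max(rep.p_values.values())
        assert all(rep.p >= p for p in rep.p_values.values())

    def test_non_psd_triple_errors(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            compare_dependent_correlations(0.9, -0.9, 0.9, 100)

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(0.6, 0.4, 0.3, 8)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.845, 0.85), (0.844999, 0.84), (-0.845, -0.85), (0.8573, 0.86)]
    )
    def test_half_up_two_decimals(self, x, expected):
        assert round_half_up(x) == expected
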