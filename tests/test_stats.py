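"""z-scoring, gated Pearson correlation, Bland-Altman agreement, group tests."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from lungmorph import (
    bland_altman_z,
    compare_groups,
    generate_correlated_pairs,
    pearson_with_gate,
    zscore,
)


class TestZscore:
    def test_already_standardized_series_unchanged(self):
        s = zscore([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(s.z, [-1, 0, 1])

    def test_normalization_identity(self):
        rng = np.random.default_rng(1)
        s = zscore(rng.uniform(10, 500, 40))
        assert s.z.mean() == pytest.approx(0, abs=1e-12)
        assert s.z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20)
        np.testing.assert_allclose(zscore(3.7 * x + 11).z, zscore(x).z, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            zscore([5.0, 5.0, 5.0])


class TestPearsonWithGate:
    @pytest.mark.parametrize(
        "r, n, expected_p",
        [(0.7866, 7, 0.0359), (0.9475, 7, 0.0012), (0.5823, 22, 0.0045)],
    )
    def test_p_values_from_t_transform(self, r, n, expected_p):
        """Two-sided p via t = r*sqrt((n-2)/(1-r^2)) with n-2 df reproduces
        the reference p-values for the given correlations and sample sizes."""
        x, y = generate_correlated_pairs(n, r, seed=4)
        report = pearson_with_gate(x, y)
        assert report.r == pytest.approx(r, abs=1e-9)
        assert round(report.p, 4) == expected_p

    def test_normality_flags_reported_not_enforced(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(0, 2.5, 50)  # decisively non-normal
        y = x + rng.normal(0, 0.1, 50)
        report = pearson_with_gate(x, y)
        assert not report.normal_x
        assert math.isfinite(report.r)  # computation still returned

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_gate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestBlandAltmanZ:
    def test_identical_series_degenerate_limits(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        ba = bland_altman_z(x, x)
        assert ba.bias == pytest.approx(0, abs=1e-12)
        assert ba.loa_low == pytest.approx(0, abs=1e-12)
        assert ba.loa_high == pytest.approx(0, abs=1e-12)

    def test_closed_form_loa_identity(self):
        """For z-scored pairs loa_high = 1.96*sqrt(2(1-r)) exactly."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x = rng.standard_normal(n)
            y = 0.5 * x + rng.standard_normal(n)
            ba = bland_altman_z(x, y)
            r = float(np.corrcoef(x, y)[0, 1])
            assert ba.bias == pytest.approx(0, abs=1e-9)
            assert ba.loa_high == pytest.approx(1.96 * math.sqrt(2 * (1 - r)), abs=1e-9)
            assert ba.loa_low == pytest.approx(-ba.loa_high, abs=1e-9)

    def test_outliers_flagged_by_index(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.1, 2.0, 2.9, 4.2, 5.0, 0.0])  # last pair disagrees wildly
        ba = bland_altman_z(x, y)
        assert 5 in ba.outside_loa

    def test_proportional_bias_slope_vanishes_for_z_scored_pairs(self):
        """cov(z_x - z_y, z_x + z_y) = var z_x - var z_y = 0: the linear
        difference-vs-mean slope is identically zero after standardization,
        so proportional bias can only appear as curvature."""
        rng = np.random.default_rng(44)
        for _ in range(20):
            x = rng.uniform(1, 100, 15)
            y = rng.uniform(1, 100, 15) + 0.5 * x
            ba = bland_altman_z(x, y)
            assert ba.proportional_bias_slope == pytest.approx(0, abs=1e-9)


class TestCompareGroups:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        cmp = compare_groups(g, g)
        assert cmp.t_stat == pytest.approx(0)
        assert cmp.p == pytest.approx(1)
        assert not cmp.welch

    def test_pooled_t_matches_closed_form(self):
        """Hand-computed pooled-variance t on 4+4 points."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
        t_expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_expected = 2 * sps.t.sf(abs(t_expected), 6)
        cmp = compare_groups(a, b)
        assert not cmp.welch  # equal variances -> Student path
        assert cmp.t_stat == pytest.approx(t_expected, abs=1e-12)
        assert cmp.p == pytest.approx(p_expected, abs=1e-12)

    def test_hundredfold_variance_ratio_triggers_welch(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 10, 10)
        cmp = compare_groups(a, b)
        assert cmp.f_p < 0.05
        assert cmp.welch

    def test_effect_sign_matches_shift_direction(self):
        rng = np.random.default_rng(31)
        a = rng.normal(0, 1, 12)
        b = rng.normal(3, 1, 12)
        cmp = compare_groups(a, b)
        assert cmp.t_stat < 0  # a below b
        assert cmp.p < 0.01

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups([1.0], [1.0, 2.0])
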