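"""Thresholding, extreme percentages, EVS statistic, Gumbel fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from normdev import (
    evs_statistic,
    extreme_percentages,
    fdr_threshold_npm,
    fit_extreme_value_distribution,
    threshold_npm,
    z_from_p,
)

_z_rows = hnp.arrays(
    float, st.integers(3, 200),
    elements=st.floats(-6, 6, allow_nan=False, width=32),
)


class TestThresholding:
    def test_all_zero_map_gives_empty_masks(self):
        neg, pos = threshold_npm(np.zeros(10), 2.6)
        assert not neg.any() and not pos.any()

    def test_strict_inequality_split_by_sign(self):
        neg, pos = threshold_npm(np.array([-3.0, 2.7, 1.0, -2.6]), 2.6)
        np.testing.assert_array_equal(np.flatnonzero(neg), [0])
        np.testing.assert_array_equal(np.flatnonzero(pos), [1])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_npm(np.zeros(5), 0.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(_z_rows)
    def test_masks_nest_across_thresholds(self, z):
        masks = [threshold_npm(z, thr) for thr in (1.96, 2.6, 3.1)]
        for (n_lo, p_lo), (n_hi, p_hi) in zip(masks, masks[1:]):
            assert not (n_hi & ~n_lo).any()
            assert not (p_hi & ~p_lo).any()
            assert not (n_lo & p_lo).any()  # disjoint tails


class TestFDR:
    def test_null_map_survives_nowhere(self):
        neg, pos = fdr_threshold_npm(np.zeros(100), q=0.05)
        assert not neg.any() and not pos.any()

    def test_single_huge_deviation_survives(self):
        z = np.zeros(1000)
        z[371] = -10.0
        neg, pos = fdr_threshold_npm(z, q=0.05)
        assert np.flatnonzero(neg).tolist() == [371]
        assert not pos.any()

    def test_matches_direct_bh_definition(self):
        """Oracle: sort two-sided p, find max i with p_(i) <= i q / m."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = rng.normal(0, 1.8, 500)
            q = 0.05
            p = 2 * stats.norm.sf(np.abs(z))
            order = np.argsort(p)
            thresh_ok = p[order] <= (np.arange(1, 501) * q / 500)
            k = np.max(np.nonzero(thresh_ok)[0]) + 1 if thresh_ok.any() else 0
            expected = np.zeros(500, bool)
            expected[order[:k]] = True
            neg, pos = fdr_threshold_npm(z, q=q)
            np.testing.assert_array_equal(neg | pos, expected)


class TestExtremePercentages:
    def test_counts_relative_to_mask(self):
        neg = np.zeros(1000, bool)
        neg[:13] = True
        pn, pp = extreme_percentages(neg, np.zeros(1000, bool))
        assert pn == pytest.approx(1.3)
        assert pp == 0.0

    def test_explicit_mask_size(self):
        neg = np.zeros(50, bool)
        neg[:5] = True
        pn, _ = extreme_percentages(neg, np.zeros(50, bool), n_mask_voxels=500)
        assert pn == pytest.approx(1.0)

    def test_tail_mean_matches_gaussian_theory(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(400, 4000))
        neg, pos = threshold_npm(Z, 2.6)
        pn, pp = extreme_percentages(neg, pos)
        expected = 100 * stats.norm.sf(2.6)
        assert pn.mean() == pytest.approx(expected, abs=0.03)
        assert pp.mean() == pytest.approx(expected, abs=0.03)


class TestEVS:
    def test_constant_map_returns_constant(self):
        assert evs_statistic(np.full(300, -1.7)) == pytest.approx(1.7)

    def test_top_one_percent_mean(self):
        z = np.zeros(200)
        z[0], z[1] = 4.0, -3.0  # ceil(0.01*200) = 2 -> mean(4, 3)
        assert evs_statistic(z) == pytest.approx(3.5)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="100"):
            evs_statistic(np.zeros(99))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_in_any_absolute_increase(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=150)
        before = evs_statistic(z)
        j = rng.integers(150)
        z2 = z.copy()
        z2[j] = np.sign(z2[j] or 1.0) * (abs(z2[j]) + rng.uniform(0.1, 3))
        assert evs_statistic(z2) >= before - 1e-12


class TestGumbelFit:
    def test_parameter_recovery(self):
        x = stats.gumbel_r.rvs(loc=3.0, scale=0.5, size=10000,
                               random_state=np.random.default_rng(2))
        fit = fit_extreme_value_distribution(x)
        assert fit.location == pytest.approx(3.0, rel=0.02)
        assert fit.scale == pytest.approx(0.5, rel=0.02)
        assert not fit.degenerate

    def test_degenerate_inputs_flagged(self):
        fit = fit_extreme_value_distribution(np.full(20, 2.5))
        assert fit.degenerate and fit.scale == 0.0

    def test_location_equivariance_under_shift(self):
        x = stats.gumbel_r.rvs(loc=1.0, scale=0.7, size=2000,
                               random_state=np.random.default_rng(3))
        f0 = fit_extreme_value_distribution(x)
        f1 = fit_extreme_value_distribution(x + 2.0)
        assert f1.location == pytest.approx(f0.location + 2.0, abs=1e-6)
        assert f1.scale == pytest.approx(f0.scale, abs=1e-6)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_extreme_value_distribution(np.r_[np.ones(15), np.nan])

    def test_gev_family_available(self):
        x = stats.gumbel_r.rvs(loc=0, scale=1, size=3000,
                               random_state=np.random.default_rng(4))
        fit = fit_extreme_value_distribution(x, family="gev")
        assert fit.shape == pytest.approx(0.0, abs=0.1)


class TestThresholdIdentities:
    @pytest.mark.parametrize("p, z, decimals", [
        (0.005, 2.6, 1), (0.001, 3.1, 1), (0.025, 1.96, 2),
    ])
    def test_per_tail_quantiles_match_conventional_z(self, p, z, decimals):
        assert round(z_from_p(p), decimals) == z
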