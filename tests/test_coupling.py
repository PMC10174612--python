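"""Cross-correlogram, rectified best lag, block-permutation null, stratification."""

import numpy as np
import pandas as pd
import pytest

from neuroglyc.coupling import (
    CouplingConfig,
    CrossCorrelogram,
    best_lag_correlation,
    cross_correlogram,
    permutation_null,
    regional_summary,
    stratified_correlation,
)

STEP_H = 1.0 / 12.0


def naive_correlogram(x, y, max_lag):
    """Independent oracle: Pearson on explicitly shifted arrays, NaN-aware."""
    out = []
    n = len(x)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = x[lag:], y[: n - lag]
        else:
            a, b = x[: n + lag], y[-lag:]
        ok = np.isfinite(a) & np.isfinite(b)
        out.append(np.corrcoef(a[ok], b[ok])[0, 1])
    return np.array(out)


class TestCrossCorrelogram:
    @pytest.mark.parametrize("with_nans", [False, True])
    def test_matches_naive_oracle(self, rng, with_nans):
        n, max_lag = 400, 20
        x = rng.normal(100, 15, n)
        y = rng.normal(50, 5, n)
        if with_nans:
            x[rng.integers(0, n, 15)] = np.nan
            y[rng.integers(0, n, 15)] = np.nan
        cc = cross_correlogram(x, y, STEP_H, max_lag * STEP_H, min_overlap=10)
        np.testing.assert_allclose(cc.r, naive_correlogram(x, y, max_lag), atol=1e-12)

    def test_swap_symmetry_exact(self, rng):
        x, y = rng.normal(size=300), rng.normal(size=300)
        ab = cross_correlogram(x, y, STEP_H, 1.0, min_overlap=10)
        ba = cross_correlogram(y, x, STEP_H, 1.0, min_overlap=10)
        np.testing.assert_array_equal(ab.r, ba.r[::-1])

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=500), rng.normal(size=500)
        base = cross_correlogram(x, y, STEP_H, 1.0)
        scaled = cross_correlogram(3.5 * x - 40, -2.0 * y + 7, STEP_H, 1.0)
        np.testing.assert_allclose(np.abs(scaled.r), np.abs(base.r), atol=1e-10)

    def test_self_correlation_peaks_at_zero(self, rng):
        x = rng.normal(size=600)
        cc = cross_correlogram(x, x, STEP_H, 1.0)
        lag, r = best_lag_correlation(cc)
        assert lag == 0.0 and r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cross_correlogram(np.full(300, 5.0), np.arange(300.0), STEP_H, 1.0)

    def test_short_overlap_undefined(self, rng):
        x, y = rng.normal(size=150), rng.normal(size=150)
        cc = cross_correlogram(x, y, STEP_H, 12.0, min_overlap=100)
        # lags pushing overlap below 100 samples are NaN
        assert np.isnan(cc.r[cc.n < 100]).all()
        assert np.isfinite(cc.r[cc.n >= 100]).all()


class TestBestLag:
    def test_rectified_criterion(self):
        lags = np.array([-2.0, 1.0])
        cc = CrossCorrelogram(lags_h=lags, r=np.array([-0.6, 0.5]),
                              n=np.array([500, 500]), step_h=STEP_H)
        assert best_lag_correlation(cc) == (-2.0, -0.6)

    def test_flat_ties_break_to_zero_lag(self):
        lags = np.arange(-3, 4) * STEP_H
        cc = CrossCorrelogram(lags_h=lags, r=np.full(7, 0.3),
                              n=np.full(7, 500), step_h=STEP_H)
        assert best_lag_correlation(cc)[0] == 0.0

    def test_shifted_synthetic_recovery(self, clean_sim):
        env, glu, _, truth = clean_sim
        x = env.values[0, 5, ::5]
        cc = cross_correlogram(x, glu.values, STEP_H, 12.0)
        lag, r = best_lag_correlation(cc)
        assert abs(lag - truth.lag_h[0]) <= STEP_H + 1e-9
        assert r > 0.5


class TestPermutationNull:
    def test_shifted_copy_extreme_p(self, rng):
        t = np.arange(1500) / 12
        s = np.cos(2 * np.pi * t / 24) + 0.4 * np.cos(2 * np.pi * t / 1.8)
        x = np.roll(s, -24)
        cfg = CouplingConfig(n_permutations=99)
        null = permutation_null(x, s, STEP_H, cfg, rng)
        assert null.p == pytest.approx(1 / 100)
        assert null.significant

    def test_too_few_blocks_rejected(self, rng):
        cfg = CouplingConfig(n_permutations=10)
        with pytest.raises(ValueError, match="blocks"):
            permutation_null(rng.normal(size=30), rng.normal(size=30), STEP_H, cfg, rng)

    def test_p_in_half_open_unit_interval(self, rng):
        cfg = CouplingConfig(n_permutations=50, min_overlap=50)
        null = permutation_null(rng.normal(size=700), rng.normal(size=700),
                                STEP_H, cfg, rng)
        assert 0 < null.p <= 1
        assert null.null_max.shape == (50,)
        assert np.all(null.lo <= null.hi)


class TestStratified:
    def test_full_mask_equals_lag_corrected_r(self, rng):
        x, y = rng.normal(size=800), rng.normal(size=800)
        cc = cross_correlogram(x, y, STEP_H, 2.0, min_overlap=50)
        lag, r = best_lag_correlation(cc)
        out = stratified_correlation(x, y, int(round(lag / STEP_H)),
                                     {"wake": np.ones(800, bool)})
        assert out["wake"] == pytest.approx(r, abs=1e-12)

    def test_empty_mask_undefined(self, rng):
        x, y = rng.normal(size=300), rng.normal(size=300)
        out = stratified_correlation(x, y, 0, {"sleep": np.zeros(300, bool)})
        assert np.isnan(out["sleep"])

    def test_small_state_undefined(self, rng):
        x, y = rng.normal(size=300), rng.normal(size=300)
        m = np.zeros(300, bool)
        m[:30] = True  # below the 50-sample floor
        assert np.isnan(stratified_correlation(x, y, 0, {"wake": m})["wake"])


class TestRegionalSummary:
    def _table(self, regions, r, r_sleep=None, r_wake=None):
        n = len(regions)
        return pd.DataFrame({
            "channel": [f"c{i}" for i in range(n)], "region": regions, "r": r,
            "r_sleep": r_sleep if r_sleep is not None else r,
            "r_wake": r_wake if r_wake is not None else r,
        })

    def test_identical_channels_degenerate(self):
        tbl = self._table(["a"] * 3 + ["b"] * 3, [0.4] * 6)
        region_df, stats = regional_summary(tbl)
        assert (region_df["r_sem"] < 1e-12).all()
        assert stats["anova"]["F"] == 0.0

    def test_single_region_skips_anova(self):
        tbl = self._table(["a"] * 4, [0.1, 0.2, 0.3, 0.4])
        _, stats = regional_summary(tbl)
        assert np.isnan(stats["anova"]["F"])
        assert "skipped" in stats["anova"]["note"]

    def test_paired_sleep_wake_direction(self, rng):
        sleep = 0.5 + rng.normal(0, 0.01, 6)
        wake = 0.2 + rng.normal(0, 0.01, 6)
        tbl = self._table(["a"] * 6, (sleep + wake) / 2, sleep, wake)
        _, stats = regional_summary(tbl)
        assert stats["paired_sleep_wake"]["a"]["t"] > 0
        assert stats["paired_sleep_wake"]["a"]["p"] < 0.05
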