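"""Feature flattening, LASSO-LAR fitting, controls, and bootstrap importance."""

import numpy as np
import pandas as pd
import pytest

from neuroglyc.decoder import (
    DecoderConfig,
    FeatureTable,
    bootstrap_importance,
    build_features,
    circadian_controls,
    fit_lasso_lar,
    saturate_target,
    shift_sweep,
    stratified_rmse,
)
from neuroglyc.synthetic import simulate_sparse_linear


class TestBuildFeatures:
    def test_column_count_and_metadata(self, aligned_default):
        ft = build_features(aligned_default)
        assert ft.X.shape[1] == 10 * 6
        assert set(ft.columns["band"]) == {"delta", "theta", "alpha", "beta",
                                           "gamma", "hfa"}

    def test_negative_shift_offsets_target_rows(self, aligned_default):
        ft0 = build_features(aligned_default, shift_h=0.0)
        ft = build_features(aligned_default, shift_h=-2.0)
        # features at row t are paired with the target 24 rows later
        np.testing.assert_array_equal(ft.row_indices, ft0.row_indices[24:])
        np.testing.assert_allclose(ft.X[:, 0], ft0.X[: len(ft.X), 0])

    def test_derivative_target(self, aligned_default):
        ft = build_features(aligned_default, target="derivative")
        y = aligned_default.glucose_series()
        np.testing.assert_allclose(ft.y[0], (y[1] - y[0]) / 5.0)

    def test_too_few_rows_rejected(self, aligned_default):
        with pytest.raises(ValueError, match="usable rows"):
            build_features(aligned_default, shift_h=-140.0)


class TestSaturate:
    def test_clipping_and_flags(self):
        y, flags = saturate_target(np.array([150.0, 160.0, 190.0]))
        np.testing.assert_array_equal(y, [150, 160, 160])
        np.testing.assert_array_equal(flags, [False, True, True])

    def test_all_below_unchanged(self):
        y, flags = saturate_target(np.array([100.0, 120.0]))
        np.testing.assert_array_equal(y, [100, 120])
        assert not flags.any()

    def test_infinite_threshold_identity(self):
        y, _ = saturate_target(np.array([100.0, 500.0]), threshold=np.inf)
        np.testing.assert_array_equal(y, [100, 500])


class TestFitLassoLar:
    def test_oracle_support_recovery_tiny_noise(self, rng):
        ft, coef = simulate_sparse_linear(noise_sd=0.02, seed=0)
        res = fit_lasso_lar(ft, DecoderConfig(), rng)
        assert res.test_r > 0.99
        assert set(np.flatnonzero(res.coef)) == set(np.flatnonzero(coef))

    def test_null_features_near_zero_r(self):
        misses = 0
        for seed in range(10):
            srng = np.random.default_rng(seed)
            X = srng.normal(size=(1500, 20))
            y = srng.normal(size=1500)
            ft = FeatureTable(X, y, pd.DataFrame({"channel": ["c"] * 20,
                                                  "band": ["hfa"] * 20}),
                              pd.date_range("2021-03-01", periods=1500, freq="5min"))
            res = fit_lasso_lar(ft, DecoderConfig(), srng)
            misses += abs(res.test_r) >= 0.15
        assert misses <= 1

    def test_sparsity_monotone_in_alpha(self, rng):
        from sklearn.linear_model import LassoLars

        ft, _ = simulate_sparse_linear(noise_sd=0.3, seed=2)
        res = fit_lasso_lar(ft, DecoderConfig(), rng)
        Xs = (ft.X - ft.X.mean(0)) / ft.X.std(0)
        counts = []
        for a in res.alphas[::10]:
            m = LassoLars(alpha=a).fit(Xs, ft.y)
            counts.append((m.coef_ != 0).sum())
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_constant_target_rejected(self, rng):
        ft, _ = simulate_sparse_linear(seed=3)
        ft.y[:] = 5.0
        with pytest.raises(ValueError, match="constant"):
            fit_lasso_lar(ft, DecoderConfig(), rng)

    def test_standardization_uses_training_rows_only(self, rng):
        ft, _ = simulate_sparse_linear(noise_sd=0.1, seed=4)
        res = fit_lasso_lar(ft, DecoderConfig(), rng)
        np.testing.assert_allclose(res.feature_mean,
                                   ft.X[res.train_rows].mean(axis=0), atol=1e-12)

    def test_prediction_invariant_to_column_rescaling(self, rng):
        ft, _ = simulate_sparse_linear(noise_sd=0.05, seed=5)
        res1 = fit_lasso_lar(ft, DecoderConfig(), np.random.default_rng(9))
        X2 = ft.X.copy()
        X2[:, 7] *= 1000.0
        ft2 = FeatureTable(X2, ft.y, ft.columns, ft.timestamps)
        res2 = fit_lasso_lar(ft2, DecoderConfig(), np.random.default_rng(9))
        np.testing.assert_allclose(res2.predictions, res1.predictions, atol=1e-6)

    def test_blocked_split_mode(self, rng):
        ft, _ = simulate_sparse_linear(noise_sd=0.1, seed=6)
        res = fit_lasso_lar(ft, DecoderConfig(blocked_split=True), rng)
        assert res.split_mode == "blocked"
        assert res.test_rows.min() > res.train_rows.max()


class TestShiftSweep:
    def test_symmetric_zero_lag_peaks_near_zero(self):
        from neuroglyc.io_timebase import align
        from neuroglyc.synthetic import SyntheticConfig, simulate

        env, glu, states, _ = simulate(SyntheticConfig(seed=9, lag_h=0.0))
        pair = align(env, glu, states)
        sw = shift_sweep(pair, np.arange(-2, 2.01, 0.5), DecoderConfig(), seed=0)
        assert abs(sw.best_shift_h) <= 0.5
        assert not sw.at_boundary

    def test_range_excluding_lead_flags_boundary(self):
        from neuroglyc.io_timebase import align
        from neuroglyc.synthetic import SyntheticConfig, simulate

        # circadian-only drive: decoding quality decays monotonically with
        # distance from the true (zero) lead, so a one-sided range must peak
        # at its boundary
        env, glu, states, _ = simulate(SyntheticConfig(
            seed=9, lag_h=0.0, ultradian=(), meal_response_mg_dl=0.0,
            hyperglycemia_episodes=0))
        pair = align(env, glu, states)
        sw = shift_sweep(pair, np.array([1.0, 2.0, 3.0]), DecoderConfig(), seed=0)
        assert sw.best_shift_h == 1.0 and sw.at_boundary


class TestStratifiedRmse:
    def _result(self, rng, n=400):
        ft, _ = simulate_sparse_linear(n_rows=n, noise_sd=0.3, seed=8)
        return fit_lasso_lar(ft, DecoderConfig(), rng), ft

    def test_homogeneous_noise_small_deltas(self, rng):
        res, ft = self._result(rng)
        masks = {"wake": np.arange(len(ft.y)) % 2 == 0,
                 "sleep": np.arange(len(ft.y)) % 2 == 1}
        out = stratified_rmse(res, masks, ft.row_indices)
        deltas = out.set_index("state")["pct_diff"]
        assert abs(deltas["wake"]) < 15 and abs(deltas["sleep"]) < 15

    def test_small_state_undefined(self, rng):
        res, ft = self._result(rng)
        m = np.zeros(len(ft.y), bool)
        m[:10] = True
        out = stratified_rmse(res, {"prandial": m}, ft.row_indices)
        assert np.isnan(out.set_index("state").loc["prandial", "rmse"])


class TestBootstrapImportance:
    def test_single_trial_binary_frequencies(self, rng):
        ft, _ = simulate_sparse_linear(noise_sd=0.1, seed=10)
        res = fit_lasso_lar(ft, DecoderConfig(), rng)
        imp = bootstrap_importance(ft, res.alpha, n_trials=1, rng=rng)
        assert set(np.unique(imp["selection_frequency"])) <= {0.0, 1.0}

    def test_frequency_tracks_coefficient_magnitude(self, rng):
        ft, coef = simulate_sparse_linear(noise_sd=0.2, seed=11)
        res = fit_lasso_lar(ft, DecoderConfig(), rng)
        imp = bootstrap_importance(ft, res.alpha, n_trials=60, rng=rng)
        r = np.corrcoef(imp["selection_frequency"], imp["median_coef"].abs())[0, 1]
        assert r > 0.5

    def test_never_selected_has_zero_median(self, rng):
        ft, coef = simulate_sparse_linear(noise_sd=0.05, seed=12)
        res = fit_lasso_lar(ft, DecoderConfig(), rng)
        imp = bootstrap_importance(ft, res.alpha, n_trials=30, rng=rng)
        zero = imp[imp["selection_frequency"] == 0]
        assert (zero["median_coef"] == 0).all()


class TestCircadianControls:
    def test_requires_three_days(self):
        from neuroglyc.io_timebase import align
        from neuroglyc.synthetic import SyntheticConfig, simulate

        env, glu, states, _ = simulate(SyntheticConfig(seed=1, duration_days=3.0))
        pair = align(env, glu, states)
        # 3.0 days of data minus edge effects is just under the 3-day floor
        with pytest.raises(ValueError, match="3 full days"):
            circadian_controls(pair, DecoderConfig())

    def test_shuffled_control_degrades(self, aligned_default):
        out = circadian_controls(aligned_default, DecoderConfig(), seed=0)
        f = out.set_index("condition")
        assert f.loc["shuffled", "mean_cv_r"] < f.loc["full", "mean_cv_r"]
        assert f.loc["shuffled", "p_vs_full"] < 0.05
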