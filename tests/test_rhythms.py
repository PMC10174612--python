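"""Wavelet coherence, circadian phase lag, and the exact band decomposition."""

import warnings

import numpy as np
import pandas as pd
import pytest

from neuroglyc.rhythms import (
    RhythmConfig,
    circadian_coherence,
    circadian_coherence_significance,
    circadian_phase_lag,
    decompose,
    phase_vs_temporal_lag,
    ultradian_coupling,
    wavelet_coherence,
)

STEP_H = 1.0 / 12.0


def _hours(days=7):
    return np.arange(int(days * 24 * 12)) / 12.0


class TestWaveletCoherence:
    def test_identical_circadian_signals(self, rng):
        t = _hours()
        x = np.cos(2 * np.pi * t / 24) + 0.05 * rng.normal(size=len(t))
        cr = wavelet_coherence(x, x.copy(), STEP_H)
        assert circadian_coherence(cr) > 0.95
        assert abs(circadian_phase_lag(cr)) < 0.2

    def test_six_hour_offset_phase(self):
        t = _hours()
        x = np.cos(2 * np.pi * (t + 6) / 24)  # x peaks 6 h before y
        y = np.cos(2 * np.pi * t / 24)
        cr = wavelet_coherence(x, y, STEP_H)
        rows = (cr.periods_h >= 16) & (cr.periods_h <= 32)
        # phase about +π/2 in the circadian band; +6 h after conversion
        assert circadian_phase_lag(cr) == pytest.approx(6.0, abs=0.5)

    def test_bounded_and_affine_invariant(self, rng):
        t = _hours(6)
        x = np.cos(2 * np.pi * t / 24) + rng.normal(size=len(t))
        y = np.cos(2 * np.pi * t / 24) + rng.normal(size=len(t))
        a = wavelet_coherence(x, y, STEP_H)
        assert a.coherence.min() >= 0 and a.coherence.max() <= 1
        b = wavelet_coherence(5 * x - 3, -0.2 * y + 11, STEP_H)
        np.testing.assert_allclose(a.coherence, b.coherence, atol=1e-9)

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="3×"):
            wavelet_coherence(rng.normal(size=200), rng.normal(size=200), STEP_H)

    def test_wraparound_warned(self):
        t = _hours()
        x = np.cos(2 * np.pi * (t + 12) / 24)
        y = np.cos(2 * np.pi * t / 24)
        cr = wavelet_coherence(x, y, STEP_H)
        with pytest.warns(UserWarning, match="wraparound"):
            ph = circadian_phase_lag(cr)
        assert abs(abs(ph) - 12.0) < 1.0


class TestCircadianCoherence:
    def test_band_variants_agree(self, clean_sim):
        env, glu, _, _ = clean_sim
        x = env.values[0, 5, ::5]
        cr = wavelet_coherence(x, glu.values, STEP_H)
        wide = circadian_coherence(cr, (16.0, 32.0))
        narrow = circadian_coherence(cr, (20.0, 28.0))
        assert abs(wide - narrow) / wide < 0.10

    def test_band_outside_grid_rejected(self, clean_sim):
        env, glu, _, _ = clean_sim
        cr = wavelet_coherence(env.values[0, 5, ::5], glu.values, STEP_H)
        with pytest.raises(ValueError, match="outside"):
            circadian_coherence(cr, (200.0, 400.0))

    def test_no_circadian_not_significant(self, rng):
        t = _hours(6)
        x = rng.normal(size=len(t))  # no circadian content
        y = np.cos(2 * np.pi * t / 24) + 0.3 * rng.normal(size=len(t))
        cfg = RhythmConfig(n_permutations=49)
        out = circadian_coherence_significance(x, y, STEP_H, cfg, rng)
        assert not out["significant"]

    def test_coupled_pair_significant(self, clean_sim, rng):
        env, glu, _, _ = clean_sim
        cfg = RhythmConfig(n_permutations=49)
        out = circadian_coherence_significance(env.values[0, 5, ::5], glu.values,
                                               STEP_H, cfg, rng)
        assert out["significant"] and out["p"] <= 0.02

    def test_nonsignificant_phase_undefined(self, clean_sim):
        env, glu, _, _ = clean_sim
        cr = wavelet_coherence(env.values[0, 5, ::5], glu.values, STEP_H)
        with pytest.warns(UserWarning, match="not significant"):
            assert np.isnan(circadian_phase_lag(cr, significant=False))


class TestDecompose:
    def test_pure_circadian_isolated(self):
        t = _hours()
        x = np.cos(2 * np.pi * t / 24)
        d = decompose(x, STEP_H)
        assert np.sqrt(np.mean((d.circadian - x) ** 2)) < 0.05
        assert np.sqrt(np.mean(d.ultradian**2)) < 0.05

    def test_two_tone_separation(self):
        t = _hours()
        circ = np.cos(2 * np.pi * t / 24)
        ultra = 0.7 * np.cos(2 * np.pi * t / 4)
        d = decompose(circ + ultra, STEP_H)
        assert np.sqrt(np.mean((d.circadian - circ) ** 2)) / np.std(circ) < 0.05
        assert np.sqrt(np.mean((d.ultradian - ultra) ** 2)) / np.std(ultra) < 0.05

    def test_reconstruction_identity(self, rng):
        x = rng.normal(100, 15, 2000).cumsum() / 30 + 100
        d = decompose(x, STEP_H)
        rel = np.sqrt(np.mean((d.reconstruct() - x) ** 2)) / np.std(x)
        assert rel < 1e-6

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="3×"):
            decompose(rng.normal(size=100), STEP_H)


class TestUltradianCoupling:
    def test_circadian_only_coupling_ablates(self, rng):
        # the two series share only a circadian tone: its removal leaves nothing
        t = _hours(6)
        x = np.cos(2 * np.pi * (t + 2) / 24) + 0.3 * rng.normal(size=len(t))
        y = np.cos(2 * np.pi * t / 24) + 0.3 * rng.normal(size=len(t))
        res = ultradian_coupling(x, y, STEP_H, run_null=False)
        assert abs(res.r_at_best) < 0.15

    def test_ablation_reduces_r(self, clean_sim):
        from neuroglyc.coupling import best_lag_correlation, cross_correlogram

        env, glu, _, _ = clean_sim
        x = env.values[0, 5, ::5]
        raw = best_lag_correlation(cross_correlogram(x, glu.values, STEP_H, 12.0))[1]
        ult = ultradian_coupling(x, glu.values, STEP_H, run_null=False)
        assert abs(ult.r_at_best) < abs(raw)


class TestPhaseVsTemporalLag:
    def test_zero_variance_undefined(self):
        df = pd.DataFrame({"phase_lag_h": [2.0] * 12, "best_lag_h": [-2.0] * 12})
        out = phase_vs_temporal_lag(df)
        assert np.isnan(out["R"]) and out["note"] == "zero variance"

    def test_too_few_channels(self):
        df = pd.DataFrame({"phase_lag_h": [1, 2, 3], "best_lag_h": [-1, -2, -3]})
        out = phase_vs_temporal_lag(df)
        assert np.isnan(out["R"]) and "channels" in out["note"]

    def test_independent_assignments_uncorrelated(self, rng):
        hits = 0
        for _ in range(20):
            df = pd.DataFrame({"phase_lag_h": rng.uniform(-6, 6, 20),
                               "best_lag_h": rng.uniform(-6, 6, 20)})
            if phase_vs_temporal_lag(df)["p"] < 0.05:
                hits += 1
        assert hits <= 4
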