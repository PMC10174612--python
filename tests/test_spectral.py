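"""Preprocessing chain: notch, Laplacian reference, Hilbert band envelopes."""

import numpy as np
import pytest

from neuroglyc.io_timebase import ChannelMeta, NeuralRecording
from neuroglyc.spectral import (
    BandDefinition,
    SpectralConfig,
    band_envelope,
    compute_envelopes,
    notch,
    rereference_laplacian,
)

FS = 512.0


def _rec(samples, fs=FS, electrode="A"):
    samples = np.atleast_2d(samples)
    chans = [ChannelMeta(f"{electrode}{i}", electrode, i)
             for i in range(samples.shape[0])]
    return NeuralRecording(samples, fs, "2021-03-01", chans)


def _t(seconds):
    return np.arange(int(seconds * FS)) / FS


class TestNotch:
    def test_line_noise_attenuated(self):
        x = np.sin(2 * np.pi * 60 * _t(60))
        out = notch(_rec(x)).samples[0]
        mid = out[int(5 * FS) : int(55 * FS)]
        assert np.abs(mid).max() < 0.10  # > 20 dB down

    def test_passband_preserved(self):
        x = np.sin(2 * np.pi * 10 * _t(60))
        out = notch(_rec(x)).samples[0]
        mid = out[int(5 * FS) : int(55 * FS)]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_unchanged(self):
        out = notch(_rec(np.full(int(10 * FS), 3.0))).samples[0]
        np.testing.assert_allclose(out, 3.0, atol=1e-6)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            notch(_rec(np.zeros(1024), fs=100.0), freqs=(60.0,))


class TestLaplacian:
    def test_common_mode_rejected(self):
        x = np.sin(2 * np.pi * 7 * _t(2))
        rec = _rec(np.tile(x, (3, 1)))
        out = rereference_laplacian(rec)
        np.testing.assert_allclose(out.samples[1], 0.0, atol=1e-12)

    def test_isolated_interior_signal_passes(self):
        x = np.sin(2 * np.pi * 7 * _t(2))
        rec = _rec(np.vstack([np.zeros_like(x), x, np.zeros_like(x)]))
        out = rereference_laplacian(rec)
        np.testing.assert_allclose(out.samples[1], x, atol=1e-12)

    def test_end_contact_bipolar_fallback(self):
        a = np.sin(2 * np.pi * 3 * _t(1))
        b = np.cos(2 * np.pi * 5 * _t(1))
        rec = _rec(np.vstack([a, b, np.zeros_like(a)]))
        out = rereference_laplacian(rec)
        np.testing.assert_allclose(out.samples[0], a - b, atol=1e-12)

    def test_single_contact_warns(self):
        rec = _rec(np.ones((1, 100)))
        with pytest.warns(UserWarning, match="single contact"):
            rereference_laplacian(rec)


class TestBandEnvelope:
    HFA = BandDefinition("hfa", 70, 170, 8)

    def test_sinusoid_amplitude_recovered(self):
        x = 5.0 * np.sin(2 * np.pi * 110 * _t(300))
        env = band_envelope(_rec(x), self.HFA, 60.0)
        np.testing.assert_allclose(env.values[0, 0], 5.0, rtol=0.05)

    def test_out_of_band_suppressed(self):
        x = 5.0 * np.sin(2 * np.pi * 10 * _t(300))
        env = band_envelope(_rec(x), self.HFA, 60.0)
        assert env.values[0, 0].max() < 0.25

    def test_amplitude_modulation_tracked(self):
        t = _t(1800)
        A = 3.0 + 2.0 * np.sin(2 * np.pi * t / 600)  # 10-min modulation
        x = A * np.sin(2 * np.pi * 110 * t)
        env = band_envelope(_rec(x), self.HFA, 60.0)
        centers = env.timestamps - np.datetime64("2021-03-01")
        sec = centers.total_seconds()
        expect = 3.0 + 2.0 * np.sin(2 * np.pi * np.asarray(sec) / 600) * np.sinc(60 / 600)
        r = np.corrcoef(env.values[0, 0], expect)[0, 1]
        assert r > 0.99

    def test_linearity_in_amplitude(self, rng):
        x = rng.normal(size=int(240 * FS))
        e1 = band_envelope(_rec(x), self.HFA, 60.0).values
        e3 = band_envelope(_rec(3 * x), self.HFA, 60.0).values
        np.testing.assert_allclose(e3, 3 * e1, rtol=1e-9)

    def test_non_negative(self, rng):
        x = rng.normal(size=int(180 * FS))
        env = band_envelope(_rec(x), self.HFA, 60.0)
        assert (env.values >= 0).all()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            band_envelope(_rec(np.zeros(4096), fs=128.0), self.HFA)

    def test_timestamps_on_window_grid(self):
        x = np.zeros(int(300 * FS))
        env = band_envelope(_rec(x), BandDefinition("gamma", 25, 70, 4), 60.0)
        offs = (env.timestamps - np.datetime64("2021-03-01")).total_seconds()
        np.testing.assert_allclose(np.asarray(offs) % 60.0, 0.0)


class TestFullChain:
    def test_recovers_programmed_envelope(self):
        from neuroglyc.synthetic import simulate_raw_voltage

        target = 10 + 3 * np.sin(2 * np.pi * np.arange(120) / 40)  # 2 h, 1-min grid
        v = simulate_raw_voltage(target, 60.0, 70, 110, fs=256.0, seed=3)
        rec = NeuralRecording(v[None, :], 256.0, "2021-03-01",
                              [ChannelMeta("A0", "A", 0)])
        cfg = SpectralConfig(reference_scheme="none", notch_freqs=(60.0,),
                             bands=(BandDefinition("hfa", 70, 110, 8),))
        env = compute_envelopes(rec, cfg)
        rec_env = env.values[0, 0]
        m = len(rec_env)
        r = np.corrcoef(rec_env, target[1 : 1 + m])[0, 1]
        assert r > 0.95

    def test_white_matter_channels_excluded(self, rng):
        chans = [ChannelMeta("A0", "A", 0, tissue="gray"),
                 ChannelMeta("A1", "A", 1, tissue="white"),
                 ChannelMeta("A2", "A", 2, tissue="gray")]
        rec = NeuralRecording(rng.normal(size=(3, int(180 * 256))), 256.0,
                              "2021-03-01", chans)
        cfg = SpectralConfig(reference_scheme="none", notch_freqs=(60.0,),
                             bands=(BandDefinition("theta", 4, 8, 4),))
        env = compute_envelopes(rec, cfg)
        assert [c.name for c in env.channels] == ["A0", "A2"]
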