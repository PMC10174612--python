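"""Raw voltage → smoothed powerband envelopes.

The preprocessing chain is: power-line notch filters (60/120/180 Hz),
Laplacian re-referencing along each electrode shaft, zero-phase Butterworth
bandpass per band, magnitude of the analytic (Hilbert) signal, and
non-overlapping 60-s boxcar averaging so each envelope sample represents one
minute of recording.  Envelope sample times are the centers of their
smoothing windows and fall on the 1-min grid of the recording clock.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io_timebase import ChannelMeta, NeuralRecording


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float
    filter_order: int = 4

    def validate(self, fs: float) -> None:
        if not (0 < self.low < self.high < fs / 2):
            raise ValueError(
                f"band {self.name} ({self.low}-{self.high} Hz) invalid for fs={fs}"
            )


#: canonical powerband set; HFA uses an 8th-order design, the rest 4th-order
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0, 4),
    BandDefinition("theta", 4.0, 8.0, 4),
    BandDefinition("alpha", 8.0, 12.0, 4),
    BandDefinition("beta", 15.0, 25.0, 4),
    BandDefinition("gamma", 25.0, 70.0, 4),
    BandDefinition("hfa", 70.0, 170.0, 8),
)


@dataclass
class SpectralConfig:
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 180.0)
    notch_q: float = 30.0
    reference_scheme: str = "laplacian"  # laplacian | bipolar | none
    smoothing_window_s: float = 60.0
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    gray_matter_only: bool = True


@dataclass
class PowerbandEnvelope:
    """Smoothed Hilbert amplitude per channel and band on a uniform grid."""

    timestamps: pd.DatetimeIndex
    values: np.ndarray  # channels × bands × time, µV
    channels: list[ChannelMeta]
    bands: list[str]
    config: SpectralConfig | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be channels × bands × time")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("envelope values must be non-negative")

    def band_index(self, name: str) -> int:
        return self.bands.index(name)

    def series(self, channel: int, band: str) -> np.ndarray:
        return self.values[channel, self.band_index(band)]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def notch(rec: NeuralRecording, freqs: tuple[float, ...] = (60.0, 120.0, 180.0),
          q: float = 30.0) -> NeuralRecording:
    """Attenuate power-line noise with zero-phase IIR notch filters."""
    nyq = rec.fs / 2
    out = rec.samples.copy()
    for f0 in freqs:
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz at or above Nyquist ({nyq} Hz)")
        b, a = signal.iirnotch(f0, q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return NeuralRecording(out, rec.fs, rec.start_time, rec.channels)


def _shaft_groups(channels: list[ChannelMeta]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, ch in enumerate(channels):
        groups.setdefault(ch.electrode, []).append(i)
    for name, idx in groups.items():
        idx.sort(key=lambda i: channels[i].contact_index)
    return groups


def rereference_laplacian(rec: NeuralRecording) -> NeuralRecording:
    """Laplacian shaft re-referencing to suppress far-field volume conduction.

    Interior contact i becomes v_i − (v_{i−1} + v_{i+1}) / 2 using its shaft
    neighbors; the two shaft-end contacts fall back to a bipolar derivation
    against their single neighbor; single-contact electrodes pass through
    with a warning.
    """
    out = np.empty_like(rec.samples)
    for shaft, idx in _shaft_groups(rec.channels).items():
        if len(idx) == 1:
            warnings.warn(f"electrode {shaft} has a single contact; passed through")
            out[idx[0]] = rec.samples[idx[0]]
            continue
        for k, i in enumerate(idx):
            if k == 0:
                out[i] = rec.samples[i] - rec.samples[idx[1]]
            elif k == len(idx) - 1:
                out[i] = rec.samples[i] - rec.samples[idx[-2]]
            else:
                out[i] = rec.samples[i] - 0.5 * (rec.samples[idx[k - 1]] + rec.samples[idx[k + 1]])
    return NeuralRecording(out, rec.fs, rec.start_time, rec.channels)


def rereference_bipolar(rec: NeuralRecording) -> NeuralRecording:
    """Bipolar derivation against the next contact on the same shaft."""
    out = rec.samples.copy()
    for _, idx in _shaft_groups(rec.channels).items():
        for k, i in enumerate(idx[:-1]):
            out[i] = rec.samples[i] - rec.samples[idx[k + 1]]
        out[idx[-1]] = rec.samples[idx[-1]] - rec.samples[idx[-2]] if len(idx) > 1 else rec.samples[idx[-1]]
    return NeuralRecording(out, rec.fs, rec.start_time, rec.channels)


def _bandpass_sos(band: BandDefinition, fs: float):
    return signal.butter(band.filter_order, [band.low, band.high], btype="band",
                         fs=fs, output="sos")


def band_envelope(
    rec: NeuralRecording,
    band: BandDefinition,
    smoothing_window_s: float = 60.0,
) -> PowerbandEnvelope:
    """Zero-phase bandpass → |Hilbert| → tiled boxcar mean (smooth + decimate).

    The stated filter order is the design order of the Butterworth bandpass;
    forward–backward application doubles the effective order and cancels
    group delay.  Envelope samples sit at the centers of consecutive
    non-overlapping windows, i.e. on the ``smoothing_window_s`` grid; the
    first and last windows (within one filter transient of the recording
    edge) are dropped.
    """
    band.validate(rec.fs)
    sos = _bandpass_sos(band, rec.fs)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    env = np.abs(signal.hilbert(filtered, axis=1))

    w = int(round(smoothing_window_s * rec.fs))
    half = w // 2
    n = rec.n_samples
    centers = np.arange(w, n - half, w)  # k·W for k ≥ 1, full window available
    if len(centers) == 0:
        raise ValueError("recording shorter than one smoothing window")
    means = np.empty((rec.n_channels, len(centers)))
    for j, c in enumerate(centers):
        means[:, j] = env[:, c - half : c - half + w].mean(axis=1)

    ts = pd.DatetimeIndex(rec.start_time + (centers / rec.fs * 1e9).astype("timedelta64[ns]"))
    return PowerbandEnvelope(
        timestamps=ts,
        values=means[:, None, :],
        channels=list(rec.channels),
        bands=[band.name],
    )


def compute_envelopes(rec: NeuralRecording, cfg: SpectralConfig | None = None) -> PowerbandEnvelope:
    """Full preprocessing chain producing the channels × bands × time envelope set."""
    cfg = cfg or SpectralConfig()
    if cfg.gray_matter_only:
        keep = [i for i, ch in enumerate(rec.channels) if ch.tissue == "gray"]
        rec = NeuralRecording(rec.samples[keep], rec.fs, rec.start_time,
                              [rec.channels[i] for i in keep])
    rec = notch(rec, cfg.notch_freqs, cfg.notch_q)
    if cfg.reference_scheme == "laplacian":
        rec = rereference_laplacian(rec)
    elif cfg.reference_scheme == "bipolar":
        rec = rereference_bipolar(rec)
    elif cfg.reference_scheme != "none":
        raise ValueError(f"unknown reference scheme: {cfg.reference_scheme}")

    per_band = [band_envelope(rec, b, cfg.smoothing_window_s) for b in cfg.bands]
    values = np.stack([p.values[:, 0, :] for p in per_band], axis=1)
    return PowerbandEnvelope(
        timestamps=per_band[0].timestamps,
        values=values,
        channels=list(rec.channels),
        bands=[b.name for b in cfg.bands],
        config=cfg,
    )
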