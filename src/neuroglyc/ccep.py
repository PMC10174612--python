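"""Cortico-cortical evoked potential (CCEP) quantification.

Single-pulse stimulation epochs (2 s, centered on the pulse) are baseline
corrected over −150 to +50 ms, the 0–10 ms stimulation artifact is blanked
with a linear bridge, and the evoked magnitude is the signed mean of the
pulse-averaged waveform over a response window (default 10–150 ms; the
window is configurable and deliberately not reconciled with narrower
conventions).  Channel groups — e.g. glucose-coupled vs uncoupled — are
compared with a two-sample t-test, and magnitude is related to per-channel
coupling strength by Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_timebase import NeuralRecording


@dataclass
class CCEPEpochSet:
    epochs: np.ndarray  # channels × pulses × time (µV)
    fs: float
    pulse_times: np.ndarray  # seconds, pulse center of each kept epoch
    stim_site: str = ""
    n_dropped: int = 0
    baseline_window_s: tuple[float, float] | None = None  # set once corrected

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be channels × pulses × time")
        if self.n_pulses < 10:
            warnings.warn(f"only {self.n_pulses} pulses; averages will be noisy")

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_pulses(self) -> int:
        return self.epochs.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in seconds, 0 at the pulse."""
        n = self.epochs.shape[2]
        return np.arange(n) / self.fs - n / self.fs / 2.0

    def mean_waveform(self) -> np.ndarray:
        return self.epochs.mean(axis=1)


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0]) & (times < window[1])


def baseline_correct(
    s: CCEPEpochSet,
    baseline_s: tuple[float, float] = (-0.150, 0.050),
    blank_s: tuple[float, float] | None = (0.0, 0.010),
) -> CCEPEpochSet:
    """Blank the stimulation artifact and subtract the per-epoch baseline mean.

    Blanking replaces 0–10 ms with a linear bridge between its endpoints;
    the magnitude window starts at 10 ms precisely so blanking cannot bias
    it.  After correction the baseline-window mean of every epoch is zero
    to machine precision.
    """
    t = s.times
    epochs = s.epochs.copy()
    if blank_s is not None:
        sel = np.flatnonzero(_window_mask(t, blank_s))
        if sel.size and sel[0] > 0 and sel[-1] + 1 < epochs.shape[2]:
            lo, hi = sel[0] - 1, sel[-1] + 1
            frac = (np.arange(1, sel.size + 1)) / (sel.size + 1)
            bridge = (
                epochs[:, :, lo, None] * (1 - frac)[None, None, :]
                + epochs[:, :, hi, None] * frac[None, None, :]
            )
            epochs[:, :, sel] = bridge
    base = _window_mask(t, baseline_s)
    if not base.any():
        raise ValueError("baseline window outside epoch")
    epochs -= epochs[:, :, base].mean(axis=2, keepdims=True)
    return CCEPEpochSet(epochs=epochs, fs=s.fs, pulse_times=s.pulse_times,
                        stim_site=s.stim_site, n_dropped=s.n_dropped,
                        baseline_window_s=baseline_s)


def epoch_and_baseline(
    rec: NeuralRecording,
    pulse_times_s: np.ndarray,
    baseline_s: tuple[float, float] = (-0.150, 0.050),
    epoch_s: float = 2.0,
    blank_s: tuple[float, float] | None = (0.0, 0.010),
    stim_site: str = "",
) -> CCEPEpochSet:
    """Cut 2-s epochs around each pulse from a continuous recording.

    Pulses whose epoch would cross a recording edge are dropped and counted
    in ``n_dropped``.
    """
    half = int(round(epoch_s * rec.fs / 2))
    n_t = 2 * half
    kept, dropped = [], 0
    for pt in np.asarray(pulse_times_s, dtype=float):
        center = int(round(pt * rec.fs))
        if center - half < 0 or center + half > rec.n_samples:
            dropped += 1
            continue
        kept.append((pt, rec.samples[:, center - half : center + half]))
    if not kept:
        raise ValueError("no pulse epoch fits inside the recording")
    if dropped:
        warnings.warn(f"dropped {dropped} pulses at recording edges")
    epochs = np.stack([e for _, e in kept], axis=1)
    times = np.array([t for t, _ in kept])
    raw = CCEPEpochSet(epochs=epochs, fs=rec.fs, pulse_times=times,
                       stim_site=stim_site, n_dropped=dropped)
    return baseline_correct(raw, baseline_s, blank_s)


def ccep_magnitude(
    s: CCEPEpochSet,
    window_s: tuple[float, float] = (0.010, 0.150),
    rectified: bool = False,
) -> np.ndarray:
    """Per-channel mean of the pulse-averaged waveform over the response window."""
    if s.baseline_window_s is None:
        raise ValueError("epochs must be baseline-corrected first")
    sel = _window_mask(s.times, window_s)
    wave = s.mean_waveform()[:, sel]
    if rectified:
        wave = np.abs(wave)
    return wave.mean(axis=1)


def compare_by_coupling(
    magnitudes: np.ndarray,
    coupled_mask: np.ndarray,
    coupling_r: np.ndarray | None = None,
    min_group: int = 5,
) -> dict:
    """Coupled-vs-uncoupled magnitude t-test and magnitude–coupling correlation."""
    magnitudes = np.asarray(magnitudes, dtype=float)
    coupled_mask = np.asarray(coupled_mask, dtype=bool)
    a, b = magnitudes[coupled_mask], magnitudes[~coupled_mask]
    out: dict = {"n_coupled": len(a), "n_uncoupled": len(b)}
    if len(a) >= min_group and len(b) >= min_group:
        t, p = stats.ttest_ind(a, b)
        out.update(t=float(t), p=float(p), df=len(a) + len(b) - 2,
                   mean_coupled=float(a.mean()), mean_uncoupled=float(b.mean()))
    else:
        out.update(t=np.nan, p=np.nan, note="fewer than 5 channels in a group")
    if coupling_r is not None:
        r_vals = np.asarray(coupling_r, dtype=float)
        ok = np.isfinite(r_vals) & np.isfinite(magnitudes)
        if ok.sum() > 2 and np.ptp(r_vals[ok]) > 0:
            R, p = stats.pearsonr(magnitudes[ok], r_vals[ok])
            out.update(pearson_r=float(R), pearson_p=float(p))
        else:
            out.update(pearson_r=np.nan, pearson_p=np.nan)
    return out
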