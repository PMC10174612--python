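"""Wavelet coherence, circadian phase lag, and circadian/ultradian decomposition.

The continuous wavelet transform uses a Morlet mother wavelet (ω₀ = 6)
evaluated in the frequency domain on a log-spaced period grid.  Coherence
follows the standard construction for bivariate series: the cross-wavelet
spectrum and the two auto-spectra are smoothed in time (Gaussian of width
equal to the scale) and across scales (boxcar of ~0.6 octave), and

    R²(s, t) = |S(Wx·Wy*/s)|² / ( S(|Wx|²/s) · S(|Wy|²/s) )

Without smoothing this ratio is identically 1; the smoothing windows are
exposed in the config.  Circadian coherence is the time- and band-mean of
R² over periods of 24 h ± 33 % (narrow 20–28 h variant available), with the
cone of influence excluded by default.  Phase (the argument of the smoothed
cross-spectrum) converts to hours via the 24-h band-center period; positive
phase lag means the neural series leads glucose.

The circadian/ultradian split is an exact complementary partition of the
Fourier spectrum at the 18 h and 36 h period edges (each frequency bin
belongs to exactly one component), so circadian + ultradian + residual
reconstructs the input to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import CouplingConfig, CouplingResult, _block_permute, couple

OMEGA0 = 6.0
#: Fourier factor for Morlet(6): period = factor × scale
FOURIER_FACTOR = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0**2))


@dataclass
class RhythmConfig:
    period_min_h: float = 0.5
    period_max_h: float = 48.0
    voices_per_octave: int = 12
    circadian_band_h: tuple[float, float] = (16.0, 32.0)  # 24 h ± 33%
    circadian_band_narrow_h: tuple[float, float] = (20.0, 28.0)
    circadian_center_h: float = 24.0
    decomp_split_h: float = 18.0  # ultradian below, circadian above
    decomp_upper_h: float = 36.0  # circadian up to here; longer → residual
    coi_policy: str = "exclude"  # exclude | include
    coherence_def: str = "magnitude_squared"  # or "magnitude"
    time_smooth_factor: float = 1.0  # Gaussian σ = factor × scale
    scale_smooth_octaves: float = 0.6
    n_permutations: int = 1000
    alpha: float = 0.05
    shuffle_segment_min: float = 30.0


@dataclass
class CoherenceResult:
    periods_h: np.ndarray
    coherence: np.ndarray  # periods × time, in [0, 1]
    phase: np.ndarray  # periods × time, radians in (−π, π]
    coi_period_h: np.ndarray  # per time point: longest period outside the COI
    periodogram: np.ndarray  # time-averaged coherence per period
    step_h: float
    config: RhythmConfig

    @property
    def in_coi(self) -> np.ndarray:
        return self.periods_h[:, None] > self.coi_period_h[None, :]


@dataclass
class BandDecomposition:
    circadian: np.ndarray
    ultradian: np.ndarray
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.circadian + self.ultradian + self.residual


# ---------------------------------------------------------------------------
# Morlet CWT and coherence
# ---------------------------------------------------------------------------


def _fill_nan(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        raise ValueError("series is entirely missing")
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def _period_grid(cfg: RhythmConfig, span_h: float) -> np.ndarray:
    top = min(cfg.period_max_h, span_h / 3.0)
    n_oct = np.log2(top / cfg.period_min_h)
    k = int(np.floor(n_oct * cfg.voices_per_octave)) + 1
    return cfg.period_min_h * 2.0 ** (np.arange(k) / cfg.voices_per_octave)


def morlet_cwt(x: np.ndarray, dt: float, scales: np.ndarray) -> np.ndarray:
    """Continuous Morlet wavelet transform via the FFT (zero-padded)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    N = int(2 ** np.ceil(np.log2(2 * n)))
    xhat = np.fft.fft(x - x.mean(), N)
    omega = 2 * np.pi * np.fft.fftfreq(N, d=dt)
    s = scales[:, None]
    psi_hat = (np.pi**-0.25) * np.sqrt(2 * np.pi * s / dt) * np.exp(
        -0.5 * (s * omega[None, :] - OMEGA0) ** 2
    ) * (omega[None, :] > 0)
    W = np.fft.ifft(xhat[None, :] * psi_hat, axis=1)[:, :n]
    return W


def _smooth_time(A: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Row-wise Gaussian smoothing (σ per row, in samples) via the FFT."""
    n = A.shape[1]
    N = int(2 ** np.ceil(np.log2(2 * n)))
    omega = 2 * np.pi * np.fft.fftfreq(N)
    G = np.exp(-0.5 * (sigmas[:, None] * omega[None, :]) ** 2)
    Ahat = np.fft.fft(A, N, axis=1)
    return np.fft.ifft(Ahat * G, axis=1)[:, :n]


def _smooth_scale(A: np.ndarray, cfg: RhythmConfig) -> np.ndarray:
    width = max(int(round(cfg.scale_smooth_octaves * cfg.voices_per_octave)), 1)
    if width <= 1:
        return A
    from scipy.ndimage import uniform_filter1d

    if np.iscomplexobj(A):
        return uniform_filter1d(A.real, width, axis=0, mode="nearest") + 1j * uniform_filter1d(
            A.imag, width, axis=0, mode="nearest"
        )
    return uniform_filter1d(A, width, axis=0, mode="nearest")


def wavelet_coherence(
    x: np.ndarray, y: np.ndarray, step_h: float, cfg: RhythmConfig | None = None
) -> CoherenceResult:
    """Smoothed Morlet wavelet coherence and phase between two series.

    Interior missing samples are linearly bridged before the transform.
    Raises if the series is shorter than 3× the longest analyzed period.
    """
    cfg = cfg or RhythmConfig()
    x, y = _fill_nan(x), _fill_nan(y)
    if x.shape != y.shape:
        raise ValueError("series must share a grid")
    span_h = len(x) * step_h
    if span_h < 3 * min(cfg.period_max_h, max(cfg.circadian_band_h[1], cfg.decomp_upper_h)):
        raise ValueError(
            f"series spans {span_h:.1f} h; need ≥ 3× the longest analyzed period"
        )

    periods = _period_grid(cfg, span_h)
    scales = periods / FOURIER_FACTOR / step_h  # in samples
    Wx = morlet_cwt(x, 1.0, scales)
    Wy = morlet_cwt(y, 1.0, scales)

    inv_s = 1.0 / scales[:, None]
    sig = cfg.time_smooth_factor * scales
    Sxx = _smooth_scale(np.abs(_smooth_time(np.abs(Wx) ** 2 * inv_s, sig)), cfg)
    Syy = _smooth_scale(np.abs(_smooth_time(np.abs(Wy) ** 2 * inv_s, sig)), cfg)
    Sxy = _smooth_scale(_smooth_time(Wx * np.conj(Wy) * inv_s, sig), cfg)

    with np.errstate(invalid="ignore", divide="ignore"):
        R2 = np.abs(Sxy) ** 2 / (Sxx * Syy)
    R2 = np.clip(np.nan_to_num(R2), 0.0, 1.0)
    coh = np.sqrt(R2) if cfg.coherence_def == "magnitude" else R2
    phase = np.angle(Sxy)

    t = np.arange(len(x)) * step_h
    edge = np.minimum(t, t[-1] - t)
    coi_period = FOURIER_FACTOR / np.sqrt(2.0) * edge

    masked = coh.copy()
    if cfg.coi_policy == "exclude":
        masked[periods[:, None] > coi_period[None, :]] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        periodogram = np.nanmean(masked, axis=1)

    return CoherenceResult(
        periods_h=periods,
        coherence=coh,
        phase=phase,
        coi_period_h=coi_period,
        periodogram=periodogram,
        step_h=step_h,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# circadian summaries
# ---------------------------------------------------------------------------


def _band_rows(cr: CoherenceResult, band_h: tuple[float, float]) -> np.ndarray:
    rows = (cr.periods_h >= band_h[0]) & (cr.periods_h <= band_h[1])
    if not rows.any():
        raise ValueError(f"band {band_h} h outside analyzed period grid")
    return rows


def circadian_coherence(
    cr: CoherenceResult, band_h: tuple[float, float] | None = None
) -> float:
    """Mean coherence over the circadian band and time (COI-excluded by default)."""
    cfg = cr.config
    rows = _band_rows(cr, band_h or cfg.circadian_band_h)
    block = cr.coherence[rows].copy()
    if cfg.coi_policy == "exclude":
        block[cr.in_coi[rows]] = np.nan
    if np.all(np.isnan(block)):
        return np.nan
    return float(np.nanmean(block))


def circadian_coherence_significance(
    x: np.ndarray,
    y: np.ndarray,
    step_h: float,
    cfg: RhythmConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Block-shuffle null for circadian coherence.

    Glucose is shuffled in 30-min blocks against the channel's own series
    (not a grand-average partner) and coherence recomputed per iteration.
    """
    cfg = cfg or RhythmConfig()
    rng = rng or np.random.default_rng()
    observed = circadian_coherence(wavelet_coherence(x, y, step_h, cfg))
    block = max(int(round(cfg.shuffle_segment_min / 60.0 / step_h)), 1)
    yf = _fill_nan(np.asarray(y, float))
    null = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        yp = _block_permute(yf, block, rng)
        null[i] = circadian_coherence(wavelet_coherence(x, yp, step_h, cfg))
    p = float((1 + np.sum(null >= observed)) / (cfg.n_permutations + 1))
    return {
        "circadian_coherence": observed,
        "p": p,
        "significant": p <= cfg.alpha,
        "null_95": float(np.nanpercentile(null, 95)),
    }


def circadian_phase_lag(
    cr: CoherenceResult,
    band_h: tuple[float, float] | None = None,
    significant: bool = True,
) -> float:
    """Coherence-weighted circular-mean circadian phase, in hours.

    Positive values mean the neural circadian component peaks before the
    glucose one (neural leads).  Conversion uses the 24-h band-center
    period, so ±12 h is a wraparound ambiguity (warned about near ±π).
    Undefined (NaN) when the circadian coherence is not significant.
    """
    if not significant:
        warnings.warn("circadian coherence not significant; phase lag undefined")
        return np.nan
    cfg = cr.config
    rows = _band_rows(cr, band_h or cfg.circadian_band_h)
    w = cr.coherence[rows].copy()
    ph = cr.phase[rows]
    if cfg.coi_policy == "exclude":
        w[cr.in_coi[rows]] = 0.0
    w = np.nan_to_num(w)
    if w.sum() == 0:
        return np.nan
    z = np.sum(w * np.exp(1j * ph))
    mean_phase = float(np.angle(z))
    if abs(mean_phase) > 0.9 * np.pi:
        warnings.warn("circadian phase near ±π: ±half-period wraparound ambiguity")
    return mean_phase / (2 * np.pi) * cfg.circadian_center_h


# ---------------------------------------------------------------------------
# circadian / ultradian decomposition
# ---------------------------------------------------------------------------


def decompose(x: np.ndarray, step_h: float, cfg: RhythmConfig | None = None) -> BandDecomposition:
    """Exact zero-phase partition into circadian, ultradian and residual.

    Frequency bins with period in [``decomp_split_h``, ``decomp_upper_h``]
    form the circadian component, shorter periods the ultradian component,
    and longer periods (plus DC) the residual, so the three sum back to the
    input exactly.  Missing interior samples are linearly bridged first and
    re-masked in the outputs.
    """
    cfg = cfg or RhythmConfig()
    x = np.asarray(x, dtype=float)
    if len(x) * step_h < 3 * cfg.decomp_upper_h:
        raise ValueError("series shorter than 3× the upper circadian period edge")
    bad = ~np.isfinite(x)
    xf = _fill_nan(x)
    n = len(xf)
    X = np.fft.rfft(xf)
    freq = np.fft.rfftfreq(n, d=step_h)  # cycles per hour
    with np.errstate(divide="ignore"):
        period = np.where(freq > 0, 1.0 / freq, np.inf)
    circ = (period >= cfg.decomp_split_h) & (period <= cfg.decomp_upper_h)
    ultra = period < cfg.decomp_split_h
    resid = ~(circ | ultra)  # DC and periods beyond the circadian edge

    def back(mask):
        out = np.fft.irfft(np.where(mask, X, 0), n)
        out[bad] = np.nan
        return out

    return BandDecomposition(circadian=back(circ), ultradian=back(ultra), residual=back(resid))


def ultradian_coupling(
    x: np.ndarray,
    y: np.ndarray,
    step_h: float,
    cfg: RhythmConfig | None = None,
    coupling_cfg: CouplingConfig | None = None,
    masks: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    run_null: bool = True,
) -> CouplingResult:
    """Coupling analysis on the ultradian components of both series."""
    cfg = cfg or RhythmConfig()
    ux = decompose(x, step_h, cfg).ultradian
    uy = decompose(y, step_h, cfg).ultradian
    return couple(ux, uy, step_h, coupling_cfg, masks=masks, rng=rng, run_null=run_null)


def phase_vs_temporal_lag(per_channel: pd.DataFrame, min_channels: int = 10) -> dict:
    """Linear relation between circadian phase lag and correlational best lag.

    Expects columns ``phase_lag_h`` (positive = neural leads), ``best_lag_h``
    (negative = neural leads) and optionally ``significant``.  The phase lag
    is mapped onto the temporal-lag sign convention (negated) before the
    Pearson correlation so that a common drive yields positive R.
    """
    df = per_channel
    if "significant" in df.columns:
        df = df[df["significant"].astype(bool)]
    df = df.dropna(subset=["phase_lag_h", "best_lag_h"])
    if len(df) < min_channels:
        return {"R": np.nan, "p": np.nan, "n": len(df),
                "note": f"only {len(df)} channels with significant circadian coherence"}
    phase_implied = -df["phase_lag_h"].to_numpy()
    lags = df["best_lag_h"].to_numpy()
    if np.ptp(phase_implied) == 0 or np.ptp(lags) == 0:
        return {"R": np.nan, "p": np.nan, "n": len(df), "note": "zero variance"}
    R, p = stats.pearsonr(phase_implied, lags)
    return {"R": float(R), "p": float(p), "n": len(df)}
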