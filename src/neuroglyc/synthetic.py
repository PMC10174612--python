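"""Synthetic neural envelopes, glucose, states and evoked epochs with known truth.

The generator emits the structure the analysis stages are built to recover:

* glucose(t) = baseline + circadian cosine + shared ultradian sinusoids
  + meal responses + hyperglycemia bumps + AR(1) noise, at 5-min cadence;
* coupled channel envelopes carry the *same* circadian/ultradian terms
  evaluated at ``t − L`` (negative L = neural leads glucose, matching the
  correlogram sign convention) scaled into envelope units, plus noise, at
  1-min cadence;
* uncoupled channels and bands carry private sinusoids at deliberately
  detuned periods plus noise;
* sleep/wake and meal annotations follow a fixed daily schedule, and a
  config switch gates the neural ultradian drive to wake periods only.

Every emitted series equals the sum of its :class:`GroundTruth` components
to machine precision (non-negativity flooring is folded into the noise
component), ultradian phases are fixed constants so the seed changes only
noise realizations, and the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccep import CCEPEpochSet
from .decoder import FeatureTable
from .io_timebase import ChannelMeta, GlucoseSeries, StateAnnotations
from .spectral import PowerbandEnvelope, _bandpass_sos

GOLDEN_ANGLE = 2.399963229728653


@dataclass(frozen=True)
class UltradianComponent:
    period_h: float
    amplitude: float  # in glucose units (mg/dL); neural copies are rescaled
    shared: bool = True


DEFAULT_ULTRADIAN: tuple[UltradianComponent, ...] = (
    # periodicities matching the observed ultradian coherence peaks
    UltradianComponent(0.7, 3.0),
    UltradianComponent(1.8, 4.0),
    UltradianComponent(7.8, 6.0),
)


@dataclass
class SyntheticConfig:
    duration_days: float = 6.0
    n_channels: int = 10
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma", "hfa")
    coupled_channels: tuple[int, ...] = (0, 1, 2)
    coupled_band: str = "hfa"
    lag_h: float = -2.8  # negative = neural leads glucose
    per_channel_lag_h: tuple[float, ...] | None = None  # overrides lag_h per coupled channel

    circadian_period_h: float = 24.0
    glucose_baseline: float = 100.0  # mg/dL
    circadian_amplitude_glucose: float = 15.0  # mg/dL
    glucose_phase_h: float = 16.0  # time-of-day of the circadian glucose peak
    ultradian: tuple[UltradianComponent, ...] = DEFAULT_ULTRADIAN

    neural_baseline: float = 20.0  # µV
    circadian_amplitude_neural: float = 2.0  # µV
    private_amplitude: float = 1.0  # µV, detuned sinusoid in uncoupled channel/bands

    noise_sd_glucose: float = 5.0
    glucose_noise_ar1: float = 0.7
    noise_sd_neural: float = 1.0

    meal_hours: tuple[float, ...] = (8.0, 13.0, 19.0)
    meal_duration_min: float = 30.0
    meal_response_mg_dl: float = 20.0
    hyperglycemia_episodes: int = 2
    hyperglycemia_magnitude: float = 80.0  # bump height; crosses 160 mg/dL

    sleep_onset_h: float = 23.0
    sleep_duration_h: float = 8.0
    wake_gated_ultradian: bool = False  # neural ultradian drive active only when awake

    start_time: str = "2021-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        # accept dict/tuple forms (YAML configs, dataclasses.asdict round-trips)
        self.ultradian = tuple(
            u if isinstance(u, UltradianComponent)
            else UltradianComponent(**u) if isinstance(u, dict)
            else UltradianComponent(*u)
            for u in self.ultradian
        )
        if self.duration_days * 24.0 < 3 * self.circadian_period_h:
            raise ValueError("duration must cover at least 3 circadian periods")
        if any(u.period_h <= 0 for u in self.ultradian):
            raise ValueError("ultradian periods must be positive")
        if self.coupled_band not in self.bands:
            raise ValueError("coupled_band must be one of bands")


@dataclass
class GroundTruth:
    """Realized components of every emitted series, plus the true structure."""

    glucose_components: dict[str, np.ndarray]  # circadian/ultradian/events/noise
    neural_components: dict[str, np.ndarray]  # each channels × bands × time (1-min)
    lag_h: dict[int, float]  # per coupled channel
    phase_offset_h: dict[int, float]  # circadian lead of each coupled channel (+ = leads)
    coupled: list[tuple[int, int]]  # (channel, band index) pairs with shared drive
    config: SyntheticConfig

    def glucose_total(self) -> np.ndarray:
        return sum(self.glucose_components.values())

    def neural_total(self) -> np.ndarray:
        return sum(self.neural_components.values())

    def predicted_r(self, channel: int, band: int, remove_circadian: bool = False,
                    decimate: int = 5, at_true_lag: bool = True) -> float:
        """Pearson r implied by the realized components (the analytic oracle).

        Pairs the envelope at the channel's true lead with glucose — i.e.
        the lag-corrected correlation the analysis should recover.  With
        ``remove_circadian`` the true circadian component is subtracted from
        both sides first — the ground-truth counterpart of the wavelet-based
        ultradian ablation.
        """
        env = self.neural_total()[channel, band]
        glu = self.glucose_total()
        if remove_circadian:
            env = env - self.neural_components["circadian"][channel, band]
            glu = glu - self.glucose_components["circadian"]
        k1 = int(round(self.lag_h.get(channel, 0.0) * 60)) if at_true_lag else 0
        idx = np.arange(len(glu)) * decimate + k1
        ok = (idx >= 0) & (idx < env.shape[-1])
        return float(np.corrcoef(env[idx[ok]], glu[ok])[0, 1])


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _ar1(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    w = rng.normal(0.0, sd * np.sqrt(max(1 - rho**2, 1e-12)), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + w[i]
    return out


def _shared_shape(cfg: SyntheticConfig):
    """Deterministic circadian + shared-ultradian shapes as callables of absolute hours."""
    T = cfg.circadian_period_h

    def circadian(t_h: np.ndarray, amplitude: float) -> np.ndarray:
        return amplitude * np.cos(2 * np.pi * (t_h - cfg.glucose_phase_h) / T)

    shared = [u for u in cfg.ultradian if u.shared]

    def ultradian(t_h: np.ndarray, scale: float) -> np.ndarray:
        out = np.zeros_like(t_h)
        for i, u in enumerate(shared):
            out += scale * u.amplitude * np.cos(2 * np.pi * t_h / u.period_h + i * GOLDEN_ANGLE)
        return out

    return circadian, ultradian


def _meal_events(cfg: SyntheticConfig, t_h: np.ndarray) -> np.ndarray:
    """Post-prandial glucose responses plus smooth hyperglycemia bumps."""
    out = np.zeros_like(t_h)
    n_days = int(np.ceil(cfg.duration_days))
    tau = 0.75  # h to response peak
    for d in range(n_days):
        for m in cfg.meal_hours:
            t0 = d * 24.0 + m
            rel = (t_h - t0) / tau
            rise = np.where(rel > 0, rel * np.exp(1 - rel), 0.0)
            out += cfg.meal_response_mg_dl * rise
    for k in range(cfg.hyperglycemia_episodes):
        t0 = (1 + 2 * k) * 24.0 + 20.0  # evening of alternating days
        if t0 > t_h[-1]:
            break
        out += cfg.hyperglycemia_magnitude * np.exp(-0.5 * ((t_h - t0) / 0.75) ** 2)
    return out


def _schedule_annotations(cfg: SyntheticConfig) -> StateAnnotations:
    start = pd.Timestamp(cfg.start_time)
    end = start + pd.Timedelta(hours=cfg.duration_days * 24.0)
    sleep, meals = [], []
    for d in range(int(np.ceil(cfg.duration_days)) + 1):
        s = start + pd.Timedelta(hours=d * 24.0 + cfg.sleep_onset_h)
        e = s + pd.Timedelta(hours=cfg.sleep_duration_h)
        if s < end:
            sleep.append((max(s, start), min(e, end)))
        for m in cfg.meal_hours:
            mt = start + pd.Timedelta(hours=d * 24.0 + m)
            if start <= mt < end:
                meals.append(mt)
    sleep = [(s, e) for s, e in sleep if (e - s) >= pd.Timedelta(hours=2)]
    return StateAnnotations.from_schedule(sleep, meals, span=(start, end),
                                          provenance="synthetic schedule")


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate(cfg: SyntheticConfig | None = None):
    """Generate (envelopes, glucose, annotations, ground truth).

    Glucose is emitted at 5-min cadence and envelopes at 1-min cadence on
    the same clock, so envelope sample 5k coincides with glucose sample k.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start_time)

    n5 = int(round(cfg.duration_days * 24 * 12))
    n1 = int(round(cfg.duration_days * 24 * 60))
    t5 = np.arange(n5) / 12.0  # hours
    t1 = np.arange(n1) / 60.0

    circadian, ultradian = _shared_shape(cfg)

    # ---- glucose -----------------------------------------------------------
    g_circ = circadian(t5, cfg.circadian_amplitude_glucose)
    g_ultra = ultradian(t5, 1.0)
    g_events = _meal_events(cfg, t5)
    g_noise = _ar1(n5, cfg.noise_sd_glucose, cfg.glucose_noise_ar1, rng)
    raw = cfg.glucose_baseline + g_circ + g_ultra + g_events + g_noise
    emitted = np.maximum(raw, 1.0)
    g_noise = g_noise + (emitted - raw)  # flooring, if any, charged to noise
    g_base = np.full(n5, cfg.glucose_baseline)

    glucose = GlucoseSeries(
        timestamps=pd.date_range(start, periods=n5, freq="5min"),
        values=emitted,
        source_flag=np.full(n5, "measured", dtype=object),
    )

    # ---- annotations and wake gate ----------------------------------------
    states = _schedule_annotations(cfg)
    env_ts = pd.date_range(start, periods=n1, freq="1min")
    gate = np.ones(n1)
    if cfg.wake_gated_ultradian:
        gate = (~states.mask(env_ts, "sleep")).astype(float)

    # ---- neural envelopes --------------------------------------------------
    C, B = cfg.n_channels, len(cfg.bands)
    scale = cfg.circadian_amplitude_neural / max(cfg.circadian_amplitude_glucose, 1e-12)
    band_idx = cfg.bands.index(cfg.coupled_band)
    lags = {}
    for j, c in enumerate(cfg.coupled_channels):
        if cfg.per_channel_lag_h is not None:
            lags[c] = float(cfg.per_channel_lag_h[j])
        else:
            lags[c] = float(cfg.lag_h)

    comp_circ = np.zeros((C, B, n1))
    comp_ultra = np.zeros((C, B, n1))
    comp_events = np.zeros((C, B, n1))
    comp_private = np.zeros((C, B, n1))
    comp_noise = np.empty((C, B, n1))
    for c in range(C):
        for b in range(B):
            comp_noise[c, b] = rng.normal(0.0, cfg.noise_sd_neural, n1)
            if c in lags and b == band_idx:
                tl = t1 - lags[c]
                comp_circ[c, b] = circadian(tl, cfg.circadian_amplitude_neural)
                comp_ultra[c, b] = ultradian(tl, scale) * gate
                # meal/hyperglycemia responses are part of the shared drive:
                # coupled activity anticipates them at the same lead
                comp_events[c, b] = _meal_events(cfg, tl) * scale
            else:
                period = 2.5 + 0.37 * c + 0.19 * b  # detuned, structural
                comp_private[c, b] = cfg.private_amplitude * np.cos(
                    2 * np.pi * t1 / period + (c * B + b) * GOLDEN_ANGLE
                )

    deterministic = cfg.neural_baseline + comp_circ + comp_ultra + comp_events + comp_private
    raw_env = deterministic + comp_noise
    emitted_env = np.maximum(raw_env, 0.0)
    comp_noise = comp_noise + (emitted_env - raw_env)
    comp_base = np.full((C, B, n1), cfg.neural_baseline)

    channels = [
        ChannelMeta(name=f"ch{c:02d}", electrode=f"E{c // 4}", contact_index=c % 4,
                    region="hypothalamus" if c in lags else "insula",
                    tissue="gray", laterality="left")
        for c in range(C)
    ]
    envelopes = PowerbandEnvelope(
        timestamps=env_ts, values=emitted_env, channels=channels, bands=list(cfg.bands)
    )

    truth = GroundTruth(
        glucose_components={"baseline": g_base, "circadian": g_circ,
                            "ultradian": g_ultra, "events": g_events, "noise": g_noise},
        neural_components={"baseline": comp_base, "circadian": comp_circ,
                           "ultradian": comp_ultra, "events": comp_events,
                           "private": comp_private, "noise": comp_noise},
        lag_h=lags,
        phase_offset_h={c: -L for c, L in lags.items()},
        coupled=[(c, band_idx) for c in lags],
        config=cfg,
    )
    return envelopes, glucose, states, truth


# ---------------------------------------------------------------------------
# evoked-potential epochs
# ---------------------------------------------------------------------------


def ccep_template(fs: float, epoch_s: float = 2.0, onset_s: float = 0.010,
                  decay_s: float = 0.060, freq_hz: float = 4.0) -> np.ndarray:
    """Damped-oscillation evoked response, peak 1.0, onset 10 ms post-pulse."""
    n = int(round(epoch_s * fs))
    t = np.arange(n) / fs - epoch_s / 2.0
    rel = t - onset_s
    h = np.where(rel >= 0, np.exp(-rel / decay_s) * np.sin(2 * np.pi * freq_hz * rel), 0.0)
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def simulate_ccep(
    n_channels: int = 12,
    coupled_set: tuple[int, ...] = (0, 1, 2, 3, 4),
    amp_coupled: float = 50.0,
    amp_uncoupled: float = 15.0,
    n_pulses: int = 50,
    noise_sd: float = 20.0,
    fs: float = 512.0,
    seed: int | np.random.Generator = 0,
) -> tuple[CCEPEpochSet, np.ndarray]:
    """Stimulation epochs with channel-dependent evoked amplitudes.

    Returns the epoch set and the per-channel true amplitude vector.
    Roughly 50 biphasic pulses is the realistic default for a clinical
    single-pulse stimulation block.
    """
    if not amp_coupled > amp_uncoupled >= 0:
        raise ValueError("need amp_coupled > amp_uncoupled >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = ccep_template(fs)
    n_t = len(template)
    amps = np.array([amp_coupled if c in coupled_set else amp_uncoupled
                     for c in range(n_channels)])
    epochs = amps[:, None, None] * template[None, None, :] + rng.normal(
        0.0, noise_sd, (n_channels, n_pulses, n_t)
    )
    pulse_times = np.arange(n_pulses) * 1.0  # 1 Hz stimulation
    return (
        CCEPEpochSet(epochs=epochs, fs=fs, pulse_times=pulse_times,
                     stim_site="left_hypothalamus"),
        amps,
    )


# ---------------------------------------------------------------------------
# decoder oracles and raw-voltage mode
# ---------------------------------------------------------------------------


def simulate_sparse_linear(
    n_rows: int = 1500,
    n_channels: int = 10,
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma", "hfa"),
    active: tuple[int, ...] = (0, 7, 23),
    coef_scale: float = 1.0,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> tuple[FeatureTable, np.ndarray]:
    """Feature table whose target is an exact sparse linear map plus noise.

    ``noise_sd`` is relative to the unit-variance linear signal, so an
    amplitude signal-to-noise of 3 corresponds to ``noise_sd = 1/3``.
    Returns the table and the true coefficient vector (decoder oracle).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = n_channels * len(bands)
    X = rng.normal(0.0, 1.0, (n_rows, p))
    coef = np.zeros(p)
    signs = [1.0 if i % 2 == 0 else -1.0 for i in range(len(active))]
    for s, j in zip(signs, active):
        coef[j] = s * coef_scale
    signal = X @ coef
    signal = signal / signal.std()
    coef = coef / (X @ coef).std() * signal.std()  # keep coef consistent with scaling
    y = signal + rng.normal(0.0, noise_sd, n_rows)
    cols = pd.DataFrame(
        {"channel": [f"ch{i // len(bands):02d}" for i in range(p)],
         "band": [bands[i % len(bands)] for i in range(p)]}
    )
    ts = pd.date_range("2021-03-01", periods=n_rows, freq="5min")
    return FeatureTable(X=X, y=y, columns=cols, timestamps=ts, target_name="level"), coef


def simulate_raw_voltage(
    envelope: np.ndarray,
    envelope_step_s: float,
    band_low: float,
    band_high: float,
    fs: float = 512.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Band-limited noise whose amplitude envelope follows a target series.

    Thin option for exercising the spectral chain: the target envelope
    (e.g. a generator HFA series on its 1-min grid) is interpolated to the
    voltage sampling rate and multiplies unit-variance bandpassed noise.
    """
    from scipy import signal as sps

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(len(envelope) * envelope_step_s * fs))
    t = np.arange(n) / fs
    env_t = (np.arange(len(envelope)) + 0.5) * envelope_step_s
    target = np.interp(t, env_t, np.asarray(envelope, float))
    from .spectral import BandDefinition

    sos = _bandpass_sos(BandDefinition("carrier", band_low, band_high, 4), fs)
    carrier = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    carrier = carrier / carrier.std()
    return target * carrier
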