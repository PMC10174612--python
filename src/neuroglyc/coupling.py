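"""Lag-resolved correlation between neural feature series and glucose.

The cross-correlogram reports, for every lag ℓ on the common grid, the
Pearson correlation between the neural series shifted by ℓ and glucose:
``r(ℓ) = corr(x(t + ℓ), y(t))``.  Negative lags therefore mean the neural
series *leads* (past neural activity pairs with current glucose).  The
"rectified" best lag maximizes |r| while the signed correlation is reported.

Significance uses a block permutation: glucose is cut into contiguous
30-min segments whose order is shuffled, preserving short-range
autocorrelation while destroying long-range alignment; the null statistic
is the maximum |r| across lags (max-statistic correction, stricter than a
per-lag null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats


@dataclass
class CouplingConfig:
    max_lag_h: float = 12.0
    shuffle_segment_min: float = 30.0
    n_permutations: int = 1000
    alpha: float = 0.05
    min_overlap: int = 100
    min_blocks: int = 10
    min_state_samples: int = 50
    per_lag_null: bool = False  # anti-conservative variant; max-statistic default


@dataclass
class CrossCorrelogram:
    lags_h: np.ndarray
    r: np.ndarray
    n: np.ndarray
    step_h: float

    def max_abs_r(self) -> float:
        a = np.abs(self.r)
        return np.nan if np.all(np.isnan(a)) else float(np.nanmax(a))


@dataclass
class PermutationNull:
    lo: np.ndarray  # per-lag 2.5th percentile
    hi: np.ndarray  # per-lag 97.5th percentile
    null_max: np.ndarray  # max-|r| per permutation
    p: float
    significant: bool


@dataclass
class CouplingResult:
    best_lag_h: float
    r_at_best: float
    correlogram: CrossCorrelogram
    null: PermutationNull | None = None
    per_state: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# correlogram
# ---------------------------------------------------------------------------


def _lagged_sums(x: np.ndarray, y: np.ndarray, max_lag: int):
    """Pairwise-complete per-lag sums via six full cross-correlations.

    NaNs are handled exactly: with validity indicators v, every per-lag
    quantity (count, Σx, Σx², Σy, Σy², Σxy over jointly-valid pairs) is a
    cross-correlation of masked arrays, so one FFT pass serves all lags.
    """
    n = len(x)
    vx = np.isfinite(x).astype(float)
    vy = np.isfinite(y).astype(float)
    x0 = np.where(vx > 0, x, 0.0)
    y0 = np.where(vy > 0, y, 0.0)

    def corr(a, b):
        full = signal.correlate(a, b, mode="full", method="auto")
        return full[n - 1 - max_lag : n + max_lag]  # lags −max_lag..+max_lag

    return {
        "n": corr(vx, vy),
        "sx": corr(x0, vy),
        "sxx": corr(x0 * x0, vy),
        "sy": corr(vx, y0),
        "syy": corr(vx, y0 * y0),
        "sxy": corr(x0, y0),
    }


def cross_correlogram(
    x: np.ndarray,
    y: np.ndarray,
    step_h: float,
    max_lag_h: float = 12.0,
    min_overlap: int = 100,
) -> CrossCorrelogram:
    """Pearson correlation of x shifted by each lag against y.

    ``step_h`` is the grid step in hours (5-min grid → 1/12).  Lags with
    fewer than ``min_overlap`` jointly-valid pairs are NaN.  All-constant
    input raises (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays on a common grid")
    for name, a in (("x", x), ("y", y)):
        vals = a[np.isfinite(a)]
        if vals.size and np.ptp(vals) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")

    max_lag = int(round(max_lag_h / step_h))
    max_lag = min(max_lag, len(x) - 1)
    # affine rescaling leaves Pearson r unchanged; standardizing keeps the
    # FFT accumulations well conditioned
    def std(a):
        v = a[np.isfinite(a)]
        return (a - v.mean()) / (v.std() if v.std() > 0 else 1.0)

    s = _lagged_sums(std(x), std(y), max_lag)
    n = np.round(s["n"]).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s["sxy"] - s["sx"] * s["sy"] / n
        varx = s["sxx"] - s["sx"] ** 2 / n
        vary = s["syy"] - s["sy"] ** 2 / n
        r = cov / np.sqrt(varx * vary)
    r[n < max(min_overlap, 2)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    lags = np.arange(-max_lag, max_lag + 1) * step_h
    return CrossCorrelogram(lags_h=lags, r=r, n=n, step_h=step_h)


def best_lag_correlation(cc: CrossCorrelogram) -> tuple[float, float]:
    """Lag maximizing |r| (rectified criterion); ties break toward |lag| → 0.

    Returns the signed Pearson correlation at that lag.
    """
    a = np.abs(cc.r)
    if np.all(np.isnan(a)):
        raise ValueError("no defined lag in correlogram")
    top = np.nanmax(a)
    candidates = np.flatnonzero(a == top)
    best = candidates[np.argmin(np.abs(cc.lags_h[candidates]))]
    return float(cc.lags_h[best]), float(cc.r[best])


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def _block_permute(y: np.ndarray, block: int, rng: np.random.Generator) -> np.ndarray:
    n = len(y)
    n_blocks = n // block
    starts = [i * block for i in range(n_blocks)]
    # remainder rides with the last block
    blocks = [y[s : s + block] for s in starts[:-1]] + [y[starts[-1] :]]
    order = rng.permutation(n_blocks)
    while np.array_equal(order, np.arange(n_blocks)):
        order = rng.permutation(n_blocks)
    return np.concatenate([blocks[i] for i in order])


def permutation_null(
    x: np.ndarray,
    y: np.ndarray,
    step_h: float,
    cfg: CouplingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationNull:
    """Block-shuffle null for the rectified cross-correlogram.

    y is partitioned into contiguous ``shuffle_segment_min`` blocks whose
    order is permuted (identity excluded); per permutation the full
    correlogram is recomputed.  The p-value of the observed max-|r| uses the
    permutation distribution of max-|r| across lags with the standard
    (1 + #{null ≥ obs}) / (n_perm + 1) estimator, so p ∈ (0, 1].
    """
    cfg = cfg or CouplingConfig()
    rng = rng or np.random.default_rng()
    block = int(round(cfg.shuffle_segment_min * 60.0 / (step_h * 3600.0)))
    block = max(block, 1)
    if len(y) // block < cfg.min_blocks:
        raise ValueError(
            f"only {len(y) // block} blocks of {block} samples; "
            f"need at least {cfg.min_blocks}"
        )

    observed = cross_correlogram(x, y, step_h, cfg.max_lag_h, cfg.min_overlap)
    obs_max = observed.max_abs_r()
    null_r = np.empty((cfg.n_permutations, len(observed.lags_h)))
    for i in range(cfg.n_permutations):
        yp = _block_permute(y, block, rng)
        cc = cross_correlogram(x, yp, step_h, cfg.max_lag_h, cfg.min_overlap)
        null_r[i] = cc.r
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(null_r, 2.5, axis=0)
        hi = np.nanpercentile(null_r, 97.5, axis=0)
        null_max = np.nanmax(np.abs(null_r), axis=1)
    if cfg.per_lag_null:
        # anti-conservative variant: compare at the observed best lag only
        idx = int(np.nanargmax(np.abs(observed.r)))
        exceed = np.sum(np.abs(null_r[:, idx]) >= obs_max)
    else:
        exceed = np.sum(null_max >= obs_max)
    p = float((1 + exceed) / (cfg.n_permutations + 1))
    return PermutationNull(lo=lo, hi=hi, null_max=null_max, p=p,
                           significant=p <= cfg.alpha)


# ---------------------------------------------------------------------------
# state stratification and regional roll-up
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray, min_n: int = 2) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_n:
        return np.nan
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def apply_lag(x: np.ndarray, y: np.ndarray, lag_steps: int):
    """Shift x by ``lag_steps`` onto y's timebase.

    Returns (x_shifted, y_trimmed, y_indices): element i of the outputs
    pairs x(t_i + ℓ) with y(t_i), where y_indices gives t_i on the original
    grid (used to evaluate state masks at glucose timestamps).
    """
    n = len(x)
    if lag_steps >= 0:
        xs, ys = x[lag_steps:], y[: n - lag_steps]
        idx = np.arange(0, n - lag_steps)
    else:
        k = -lag_steps
        xs, ys = x[: n - k], y[k:]
        idx = np.arange(k, n)
    return xs, ys, idx


def stratified_correlation(
    x: np.ndarray,
    y: np.ndarray,
    best_lag_steps: int,
    masks: dict[str, np.ndarray],
    min_samples: int = 50,
) -> dict[str, float]:
    """Lag-corrected Pearson r within each behavioral state.

    Masks are evaluated at the glucose timestamps of the lag-corrected
    pairs; states with fewer than ``min_samples`` valid pairs are NaN.
    """
    xs, ys, idx = apply_lag(np.asarray(x, float), np.asarray(y, float), best_lag_steps)
    out: dict[str, float] = {}
    for label, m in masks.items():
        sel = m[idx]
        out[label] = _pearson(xs[sel], ys[sel], min_n=min_samples)
    return out


def regional_summary(per_channel: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Region-level roll-up of per-channel coupling results.

    ``per_channel`` needs columns: channel, region, r (lag-corrected),
    r_sleep, r_wake.  Returns (region table with mean ± SEM per state,
    stats dict with per-region paired sleep/wake t-tests and a one-way
    ANOVA of r across regions).
    """
    required = {"channel", "region", "r", "r_sleep", "r_wake"}
    if not required.issubset(per_channel.columns):
        raise ValueError(f"per_channel must have columns {sorted(required)}")

    rows = []
    stats_out: dict = {"paired_sleep_wake": {}}
    for region, grp in per_channel.groupby("region"):
        row = {"region": region, "n_channels": len(grp)}
        for col in ("r", "r_sleep", "r_wake"):
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{col}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{col}_sem"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                 if len(vals) > 1 else 0.0 if len(vals) == 1 else np.nan)
        rows.append(row)
        paired = grp[["r_sleep", "r_wake"]].dropna()
        if len(paired) > 1 and not np.allclose(paired["r_sleep"], paired["r_wake"]):
            t, p = stats.ttest_rel(paired["r_sleep"], paired["r_wake"])
            stats_out["paired_sleep_wake"][region] = {"t": float(t), "p": float(p),
                                                      "df": len(paired) - 1}
        else:
            stats_out["paired_sleep_wake"][region] = {"t": np.nan, "p": np.nan,
                                                      "df": max(len(paired) - 1, 0)}

    groups = [g["r"].dropna().to_numpy() for _, g in per_channel.groupby("region")]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) > 1:
        if np.ptp(np.concatenate(groups)) == 0:
            stats_out["anova"] = {"F": 0.0, "p": 1.0, "note": "no variance across channels"}
        else:
            F, p = stats.f_oneway(*groups)
            stats_out["anova"] = {"F": float(F), "p": float(p)}
    else:
        stats_out["anova"] = {"F": np.nan, "p": np.nan,
                              "note": "single region; ANOVA skipped"}
    return pd.DataFrame(rows), stats_out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def couple(
    x: np.ndarray,
    y: np.ndarray,
    step_h: float,
    cfg: CouplingConfig | None = None,
    masks: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    run_null: bool = True,
) -> CouplingResult:
    """Full coupling analysis of one feature series against glucose.

    Applies identically to glucose levels and to the glucose derivative —
    the caller chooses the target series.
    """
    cfg = cfg or CouplingConfig()
    cc = cross_correlogram(x, y, step_h, cfg.max_lag_h, cfg.min_overlap)
    lag_h, r = best_lag_correlation(cc)
    null = permutation_null(x, y, step_h, cfg, rng) if run_null else None
    per_state = {}
    if masks:
        per_state = stratified_correlation(
            x, y, int(round(lag_h / step_h)), masks, cfg.min_state_samples
        )
    return CouplingResult(best_lag_h=lag_h, r_at_best=r, correlogram=cc,
                          null=null, per_state=per_state)
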