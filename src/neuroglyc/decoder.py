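"""Spectro-spatial LASSO-LAR glucose decoder.

The feature space flattens the channels × bands × time envelope array into
a table of 6N columns; the target is glucose (or its derivative) at a
configurable temporal shift (negative shift = neural features precede the
target, i.e. proactive decoding).  The penalty weight α is chosen by 5-fold
cross-validation on the training split, scoring Pearson R between actual
and predicted values; the least-angle path makes the sweep over the α grid
cheap because LASSO coefficients are piecewise linear in α.

Controls probe whether performance reduces to circadian autocorrelation:
a 1-h block-shuffled target (alignment destroyed), a time-of-day mean
predictor (pure circadian), and decoding of the circadian component and of
the ultradian deviation separately.  Channel importance comes from a
bootstrap over rows: a column is flagged when LASSO selects it in at least
99 % of refits.

Two split modes exist because random row splits of autocorrelated series
inflate R: ``blocked_split=False`` (random rows, the headline mode) and
``blocked_split=True`` (contiguous tail held out).  Reports name the mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoLars, lars_path

from .io_timebase import AlignedPair
from .rhythms import RhythmConfig, decompose


@dataclass
class DecoderConfig:
    test_fraction: float = 0.20
    cv_folds: int = 5
    n_alphas: int = 50
    alpha_decades: float = 4.0
    hyperglycemia_threshold: float = 160.0
    min_rows: int = 200
    blocked_split: bool = False
    shuffle_block_h: float = 1.0  # for the shuffled-target control

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class FeatureTable:
    X: np.ndarray  # rows × columns
    y: np.ndarray
    columns: pd.DataFrame  # per column: channel, band
    timestamps: pd.DatetimeIndex  # per row (target timestamps)
    target_name: str = "level"
    row_indices: np.ndarray | None = None  # rows' positions on the aligned grid

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column metadata must match X")
        if self.row_indices is None:
            self.row_indices = np.arange(len(self.y))


@dataclass
class DecoderResult:
    alpha: float
    coef: np.ndarray  # in standardized-feature space
    intercept: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    columns: pd.DataFrame
    test_r: float
    test_rmse: float
    per_fold_r: np.ndarray  # CV folds at the chosen alpha
    alphas: np.ndarray
    cv_mean_r: np.ndarray  # mean CV score per alpha
    train_rows: np.ndarray
    test_rows: np.ndarray
    predictions: np.ndarray  # on test rows
    y_test: np.ndarray
    split_mode: str = "random"

    @property
    def nonzero(self) -> pd.DataFrame:
        sel = np.flatnonzero(self.coef != 0)
        out = self.columns.iloc[sel].copy()
        out["coef"] = self.coef[sel]
        return out.reset_index(drop=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.feature_mean) / self.feature_sd
        return Xs @ self.coef + self.intercept


@dataclass
class ShiftSweepResult:
    shifts_h: np.ndarray
    mean_cv_r: np.ndarray
    sem_cv_r: np.ndarray
    best_shift_h: float
    at_boundary: bool


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------


def build_features(
    aligned: AlignedPair,
    target: str = "level",
    shift_h: float = 0.0,
    gray_only: bool = True,
    cfg: DecoderConfig | None = None,
) -> FeatureTable:
    """Flatten the envelope array and pair it with a (possibly shifted) target.

    Features at row t are paired with the target at t − shift, so a negative
    shift makes neural activity precede the target (proactive decoding).
    Rows with any missing side are dropped.  Standardization happens inside
    the fit, from training-set statistics only.
    """
    cfg = cfg or DecoderConfig()
    keep = [i for i, ch in enumerate(aligned.channels)
            if not gray_only or ch.tissue == "gray"]
    neural = aligned.neural[keep]  # C × B × T
    C, B, T = neural.shape
    X_full = neural.reshape(C * B, T).T  # T × (C·B), channel-major

    y_full = aligned.glucose_series()
    if target == "derivative":
        step_min = aligned.cadence_s / 60.0
        dv = np.full(T, np.nan)
        dv[1:] = np.diff(y_full) / step_min
        y_full = dv
    elif target != "level":
        raise ValueError("target must be 'level' or 'derivative'")

    k = int(round(shift_h * 3600.0 / aligned.cadence_s))
    feat_idx = np.arange(T)
    targ_idx = feat_idx - k
    ok = (targ_idx >= 0) & (targ_idx < T)
    feat_idx, targ_idx = feat_idx[ok], targ_idx[ok]
    rows_ok = (
        aligned.valid[feat_idx]
        & np.isfinite(X_full[feat_idx]).all(axis=1)
        & np.isfinite(y_full[targ_idx])
    )
    feat_idx, targ_idx = feat_idx[rows_ok], targ_idx[rows_ok]
    if len(feat_idx) < cfg.min_rows:
        raise ValueError(f"only {len(feat_idx)} usable rows; need {cfg.min_rows}")

    cols = pd.DataFrame(
        {"channel": [aligned.channels[keep[i // B]].name for i in range(C * B)],
         "band": [aligned.bands[i % B] for i in range(C * B)]}
    )
    return FeatureTable(
        X=X_full[feat_idx],
        y=y_full[targ_idx],
        columns=cols,
        timestamps=aligned.grid[targ_idx],
        target_name=target,
        row_indices=targ_idx,
    )


def saturate_target(y: np.ndarray, threshold: float = 160.0) -> tuple[np.ndarray, np.ndarray]:
    """Clip hyperglycemic values to the threshold; flag the clipped times.

    The decoder then identifies hyperglycemic periods rather than chasing
    exact values in the range where the spectral–glucose relation is
    non-linear.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    flags = y >= threshold
    return np.minimum(y, threshold), flags


# ---------------------------------------------------------------------------
# LASSO-LAR fitting with CV alpha selection
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _coefs_at(alphas_path: np.ndarray, coefs_path: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """LASSO coefficients at arbitrary α by piecewise-linear path interpolation."""
    # alphas_path is decreasing; np.interp needs increasing x
    rev_a = alphas_path[::-1]
    rev_c = coefs_path[:, ::-1]
    out = np.empty((len(grid), coefs_path.shape[0]))
    for j in range(coefs_path.shape[0]):
        out[:, j] = np.interp(grid, rev_a, rev_c[j], left=rev_c[j, 0], right=0.0)
    out[grid >= alphas_path[0]] = 0.0
    return out  # n_grid × p


def _standardize(X: np.ndarray, mean=None, sd=None):
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _alpha_grid(Xs: np.ndarray, y: np.ndarray, cfg: DecoderConfig) -> np.ndarray:
    alpha_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y)
    return np.geomspace(alpha_max, alpha_max * 10 ** (-cfg.alpha_decades), cfg.n_alphas)


def _split_rows(n: int, cfg: DecoderConfig, rng: np.random.Generator):
    n_test = max(int(round(n * cfg.test_fraction)), 1)
    if cfg.blocked_split:
        test = np.arange(n - n_test, n)
        train = np.arange(n - n_test)
    else:
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
    return train, test


def fit_lasso_lar(
    ft: FeatureTable,
    cfg: DecoderConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DecoderResult:
    """Train/test split, 5-fold CV over the α grid, refit, held-out evaluation."""
    cfg = cfg or DecoderConfig()
    rng = rng or np.random.default_rng()
    y = np.asarray(ft.y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant; decoding undefined")
    train, test = _split_rows(len(y), cfg, rng)
    X_tr, y_tr = ft.X[train], y[train]

    Xs_tr, mean, sd = _standardize(X_tr)
    grid = _alpha_grid(Xs_tr, y_tr, cfg)

    folds = _kfold(len(train), cfg.cv_folds, rng)
    scores = np.zeros((cfg.cv_folds, len(grid)))
    for fi, (fit_idx, val_idx) in enumerate(folds):
        Xf, mf, sf = _standardize(X_tr[fit_idx])
        yf = y_tr[fit_idx]
        alphas_path, _, coefs_path = lars_path(Xf, yf - yf.mean(), method="lasso",
                                               alpha_min=float(grid[-1]))
        W = _coefs_at(alphas_path, coefs_path, grid)  # n_grid × p
        Xv = (X_tr[val_idx] - mf) / sf
        preds = Xv @ W.T + yf.mean()
        for gi in range(len(grid)):
            scores[fi, gi] = _pearson(preds[:, gi], y_tr[val_idx])
    mean_scores = scores.mean(axis=0)
    # near-ties (within numerical score tolerance) resolve toward the
    # larger alpha, i.e. the sparser model
    best = np.max(mean_scores)
    best_gi = int(np.flatnonzero(mean_scores >= best - 1e-4)[0])
    alpha = float(grid[best_gi])

    model = LassoLars(alpha=alpha, fit_intercept=True)
    model.fit(Xs_tr, y_tr)
    Xs_test = (ft.X[test] - mean) / sd
    pred = model.predict(Xs_test)
    r = _pearson(pred, y[test])
    rmse = float(np.sqrt(np.mean((pred - y[test]) ** 2)))

    return DecoderResult(
        alpha=alpha,
        coef=model.coef_.copy(),
        intercept=float(model.intercept_),
        feature_mean=mean,
        feature_sd=sd,
        columns=ft.columns,
        test_r=r,
        test_rmse=rmse,
        per_fold_r=scores[:, best_gi].copy(),
        alphas=grid,
        cv_mean_r=mean_scores,
        train_rows=train,
        test_rows=test,
        predictions=pred,
        y_test=y[test].copy(),
        split_mode="blocked" if cfg.blocked_split else "random",
    )


def _kfold(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    return [(np.sort(np.concatenate(folds[:i] + folds[i + 1 :])), np.sort(folds[i]))
            for i in range(k)]


# ---------------------------------------------------------------------------
# shift sweep
# ---------------------------------------------------------------------------


def shift_sweep(
    aligned: AlignedPair,
    shifts_h: np.ndarray,
    cfg: DecoderConfig | None = None,
    target: str = "level",
    seed: int = 0,
) -> ShiftSweepResult:
    """Refit the full decoder at every temporal shift with a fresh seeded split.

    Negative shifts mean current neural data predicts future glucose
    (proactive decoding).  The per-shift score is the mean cross-validated
    Pearson R at that shift's chosen α, with SEM across folds.
    """
    cfg = cfg or DecoderConfig()
    shifts_h = np.asarray(shifts_h, dtype=float)
    means, sems = np.empty(len(shifts_h)), np.empty(len(shifts_h))
    children = np.random.SeedSequence(seed).spawn(len(shifts_h))
    for i, sh in enumerate(shifts_h):
        ft = build_features(aligned, target=target, shift_h=float(sh), cfg=cfg)
        res = fit_lasso_lar(ft, cfg, np.random.default_rng(children[i]))
        means[i] = res.per_fold_r.mean()
        sems[i] = res.per_fold_r.std(ddof=1) / np.sqrt(len(res.per_fold_r))
    best = int(np.argmax(means))
    return ShiftSweepResult(
        shifts_h=shifts_h,
        mean_cv_r=means,
        sem_cv_r=sems,
        best_shift_h=float(shifts_h[best]),
        at_boundary=best in (0, len(shifts_h) - 1),
    )


# ---------------------------------------------------------------------------
# circadian-dependency controls
# ---------------------------------------------------------------------------


def _time_of_day_mean(timestamps: pd.DatetimeIndex, y: np.ndarray,
                      fit_rows: np.ndarray, cadence_s: float = 300.0) -> np.ndarray:
    """Predict every row by the mean of its 5-min-of-day bin over fit rows."""
    seconds = (timestamps.hour * 3600 + timestamps.minute * 60 + timestamps.second)
    bins = (np.asarray(seconds) // int(cadence_s)).astype(int)
    table: dict[int, float] = {}
    for b in np.unique(bins[fit_rows]):
        table[b] = float(np.mean(y[fit_rows][bins[fit_rows] == b]))
    overall = float(np.mean(y[fit_rows]))
    return np.array([table.get(b, overall) for b in bins])


def circadian_controls(
    aligned: AlignedPair,
    cfg: DecoderConfig | None = None,
    rhythm_cfg: RhythmConfig | None = None,
    seed: int = 0,
    shift_h: float = 0.0,
) -> pd.DataFrame:
    """Control battery for circadian dependency of decoder performance.

    Rows: ``full`` (measured glucose), ``shuffled`` (1-h block-shuffled
    target), ``circadian_control`` (time-of-day mean predictor, no neural
    data), ``circadian_target`` and ``ultradian_target`` (decoding the
    wavelet circadian component / the deviation from it).  Each reports
    per-fold CV Pearson R and a two-sample t-test against the full model
    across folds.  All conditions run at the caller's (optimal) temporal
    shift.  Needs ≥ 3 full days for the time-of-day average.
    """
    cfg = cfg or DecoderConfig()
    rhythm_cfg = rhythm_cfg or RhythmConfig()
    ft = build_features(aligned, target="level", shift_h=shift_h, cfg=cfg)
    span_days = (ft.timestamps[-1] - ft.timestamps[0]).total_seconds() / 86400.0
    if span_days < 3.0:
        raise ValueError("need at least 3 full days for the time-of-day average")
    ss = np.random.SeedSequence(seed).spawn(5)
    step_h = aligned.cadence_s / 3600.0

    rows = []
    full = fit_lasso_lar(ft, cfg, np.random.default_rng(ss[0]))
    rows.append(("full", full.per_fold_r, full.test_r))

    # shuffled-target control: destroy alignment in 1-h blocks
    rng = np.random.default_rng(ss[1])
    block = max(int(round(cfg.shuffle_block_h * 3600.0 / aligned.cadence_s)), 1)
    from .coupling import _block_permute

    y_shuf = _block_permute(ft.y.copy(), block, rng)
    ft_shuf = FeatureTable(ft.X, y_shuf, ft.columns, ft.timestamps,
                           "level_shuffled", ft.row_indices)
    shuf = fit_lasso_lar(ft_shuf, cfg, rng)
    rows.append(("shuffled", shuf.per_fold_r, shuf.test_r))

    # circadian control: time-of-day mean predictor, scored on the same folds
    rng = np.random.default_rng(ss[2])
    train, test = _split_rows(len(ft.y), cfg, rng)
    folds = _kfold(len(train), cfg.cv_folds, rng)
    fold_r = []
    for fit_idx, val_idx in folds:
        pred = _time_of_day_mean(ft.timestamps, ft.y, train[fit_idx], aligned.cadence_s)
        fold_r.append(_pearson(pred[train[val_idx]], ft.y[train[val_idx]]))
    pred_all = _time_of_day_mean(ft.timestamps, ft.y, train, aligned.cadence_s)
    rows.append(("circadian_control", np.array(fold_r),
                 _pearson(pred_all[test], ft.y[test])))

    # component targets from the wavelet band split of glucose
    parts = decompose(aligned.glucose_series(), step_h, rhythm_cfg)
    circ_target = (parts.circadian + parts.residual)[ft.row_indices]
    ultra_target = parts.ultradian[ft.row_indices]
    for name, target, child in (("circadian_target", circ_target, 3),
                                ("ultradian_target", ultra_target, 4)):
        ft_c = FeatureTable(ft.X, target, ft.columns, ft.timestamps, name, ft.row_indices)
        res = fit_lasso_lar(ft_c, cfg, np.random.default_rng(ss[child]))
        rows.append((name, res.per_fold_r, res.test_r))

    out = []
    full_folds = rows[0][1]
    for name, fold_vals, test_r in rows:
        if name == "full" or np.allclose(fold_vals, full_folds):
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(full_folds, fold_vals)
        out.append({"condition": name, "mean_cv_r": float(np.mean(fold_vals)),
                    "sem_cv_r": float(np.std(fold_vals, ddof=1) / np.sqrt(len(fold_vals))),
                    "test_r": float(test_r), "t_vs_full": t, "p_vs_full": p,
                    "fold_r": list(np.round(fold_vals, 6))})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# state-stratified error and bootstrap importance
# ---------------------------------------------------------------------------


def stratified_rmse(
    result: DecoderResult,
    masks: dict[str, np.ndarray],
    row_indices: np.ndarray,
    min_rows: int = 30,
) -> pd.DataFrame:
    """Per-state RMSE of test-row predictions and percent difference vs overall."""
    test_grid = row_indices[result.test_rows]
    err = result.predictions - result.y_test
    overall = float(np.sqrt(np.mean(err**2)))
    rows = [{"state": "all", "n": len(err), "rmse": overall, "pct_diff": 0.0}]
    for label, m in masks.items():
        sel = m[test_grid]
        if sel.sum() < min_rows:
            rows.append({"state": label, "n": int(sel.sum()),
                         "rmse": np.nan, "pct_diff": np.nan})
            continue
        rmse = float(np.sqrt(np.mean(err[sel] ** 2)))
        rows.append({"state": label, "n": int(sel.sum()), "rmse": rmse,
                     "pct_diff": 100.0 * (rmse - overall) / overall})
    return pd.DataFrame(rows)


def bootstrap_importance(
    ft: FeatureTable,
    alpha: float,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    freq_threshold: float = 0.99,
) -> pd.DataFrame:
    """Selection frequency and median coefficient over row-resampled refits.

    Rows are resampled with replacement (same size) and the decoder refit
    at the fixed, previously chosen α — the cost-saving alternative to
    nesting the full CV inside every trial.  A column is significant when
    selected in at least ``freq_threshold`` of trials; a channel is
    significant when any of its bands is.
    """
    rng = rng or np.random.default_rng()
    n, p = ft.X.shape
    counts = np.zeros(p)
    coefs = np.zeros((n_trials, p))
    for t in range(n_trials):
        idx = rng.integers(0, n, n)
        Xb, yb = ft.X[idx], ft.y[idx]
        Xs, _, _ = _standardize(Xb)
        model = LassoLars(alpha=alpha, fit_intercept=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, yb)
        sel = model.coef_ != 0
        counts += sel
        coefs[t] = model.coef_
    freq = counts / n_trials
    med = np.median(coefs, axis=0)
    med[freq == 0] = 0.0
    out = ft.columns.copy()
    out["selection_frequency"] = freq
    out["median_coef"] = med
    out["significant"] = freq >= freq_threshold
    chan_sig = out.groupby("channel")["significant"].transform("any")
    out["channel_significant"] = chan_sig
    return out
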