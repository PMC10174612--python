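"""End-to-end orchestration: simulate → preprocess → couple → rhythms → decode.

A run is driven by a single YAML config whose hash, seeds and per-stage
output checksums land in a JSON manifest, so a rerun with the same config
and seed reproduces every stochastic output bit for bit.  The ``neuroglyc``
console script exposes each stage as a subcommand plus ``run-all``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccep import ccep_magnitude
from .coupling import CouplingConfig, couple
from .decoder import (
    DecoderConfig,
    bootstrap_importance,
    build_features,
    circadian_controls,
    fit_lasso_lar,
    saturate_target,
    shift_sweep,
    stratified_rmse,
)
from .io_timebase import (
    align,
    interpolate_gaps,
    read_annotations,
    read_glucose,
    write_annotations,
    write_glucose,
)
from .rhythms import (
    RhythmConfig,
    circadian_coherence_significance,
    circadian_phase_lag,
    phase_vs_temporal_lag,
    ultradian_coupling,
    wavelet_coherence,
)
from .synthetic import SyntheticConfig, simulate


@dataclass
class RunConfig:
    out_dir: str = "neuroglyc_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    rhythms: RhythmConfig = field(default_factory=RhythmConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    glucose_path: str | None = None  # external inputs override simulation
    features_path: str | None = None
    states_path: str | None = None
    target: str = "level"
    n_rhythm_permutations: int = 100  # per-channel coherence null size for runs
    run_sweep: bool = False
    sweep_range_h: tuple[float, float, float] = (-6.0, 6.0, 0.5)
    run_controls: bool = False
    run_importance: bool = False
    n_bootstrap: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (("synthetic", SyntheticConfig), ("coupling", CouplingConfig),
                         ("rhythms", RhythmConfig), ("decoder", DecoderConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        cfg = cls(**kwargs)
        for p in (cfg.glucose_path, cfg.features_path, cfg.states_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input missing: {p}")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_features_csv(path: str) -> tuple:
    """Long-format envelope CSV (time, channel, band, value) → envelope object."""
    from .io_timebase import ChannelMeta
    from .spectral import PowerbandEnvelope

    df = pd.read_csv(path, parse_dates=["time"])
    chans = sorted(df["channel"].unique())
    bands = sorted(df["band"].unique())
    times = pd.DatetimeIndex(sorted(df["time"].unique()))
    cube = np.full((len(chans), len(bands), len(times)), np.nan)
    ci = {c: i for i, c in enumerate(chans)}
    bi = {b: i for i, b in enumerate(bands)}
    ti = {t: i for i, t in enumerate(times)}
    for row in df.itertuples():
        cube[ci[row.channel], bi[row.band], ti[row.time]] = row.value
    meta = [ChannelMeta(name=c) for c in chans]
    return PowerbandEnvelope(timestamps=times, values=cube, channels=meta, bands=bands)


def write_features_csv(path: str | Path, envelopes) -> None:
    rows = []
    for ci, ch in enumerate(envelopes.channels):
        for bi, band in enumerate(envelopes.bands):
            vals = envelopes.values[ci, bi]
            rows.append(pd.DataFrame({"time": envelopes.timestamps, "channel": ch.name,
                                      "band": band, "value": vals}))
    pd.concat(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run stages
# ---------------------------------------------------------------------------


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "warnings": [],
        "stages": {},
        "split_mode": "blocked" if cfg.decoder.blocked_split else "random",
    }
    timer = time.time()
    root_ss = np.random.SeedSequence(cfg.seed)
    rngs = {name: np.random.default_rng(child)
            for name, child in zip(("sim", "couple", "rhythm", "decode"), root_ss.spawn(4))}

    # ---- inputs ------------------------------------------------------------
    if cfg.glucose_path and cfg.features_path:
        glucose = interpolate_gaps(read_glucose(cfg.glucose_path))
        envelopes = _load_features_csv(cfg.features_path)
        states = read_annotations(cfg.states_path) if cfg.states_path else None
        truth = None
    else:
        sim_cfg = SyntheticConfig(**{**asdict(cfg.synthetic), "seed": cfg.seed})
        envelopes, glucose, states, truth = simulate(sim_cfg)
        write_glucose(out / "glucose.csv", glucose)
        write_annotations(out / "states.csv", states)
        write_features_csv(out / "features.csv", envelopes)
    manifest["stages"]["inputs"] = {"elapsed_s": round(time.time() - timer, 2)}

    aligned = align(envelopes, glucose, states)
    step_h = aligned.cadence_s / 3600.0
    y = aligned.glucose_series()
    if cfg.target == "derivative":
        from .io_timebase import glucose_derivative

        d = glucose_derivative(glucose)
        y = np.concatenate([[np.nan], d.values])
        y[~aligned.valid] = np.nan

    # ---- coupling ----------------------------------------------------------
    timer = time.time()
    band_idx = aligned.bands.index("hfa") if "hfa" in aligned.bands else 0
    coupling_rows, correlograms = [], []
    for ci, ch in enumerate(aligned.channels):
        x = aligned.feature_series(ci, band_idx)
        res = couple(x, y, step_h, cfg.coupling, masks=aligned.masks,
                     rng=rngs["couple"])
        coupling_rows.append({
            "channel": ch.name, "region": ch.region,
            "best_lag_h": res.best_lag_h, "r": res.r_at_best,
            "p": res.null.p if res.null else np.nan,
            "significant": res.null.significant if res.null else np.nan,
            "r_sleep": res.per_state.get("sleep", np.nan),
            "r_wake": res.per_state.get("wake", np.nan),
            "r_pre_prandial": res.per_state.get("pre_prandial", np.nan),
            "r_prandial": res.per_state.get("prandial", np.nan),
        })
        correlograms.append(pd.DataFrame({"channel": ch.name,
                                          "lag_h": res.correlogram.lags_h,
                                          "r": res.correlogram.r}))
    coupling_df = pd.DataFrame(coupling_rows)
    coupling_df.to_csv(out / "coupling.csv", index=False)
    pd.concat(correlograms).to_csv(out / "correlograms.csv", index=False)
    manifest["stages"]["coupling"] = {"elapsed_s": round(time.time() - timer, 2),
                                      "n_channels": len(coupling_df)}

    # ---- rhythms -----------------------------------------------------------
    timer = time.time()
    rhythm_cfg = cfg.rhythms
    rhythm_rows = []
    perm_cfg = RhythmConfig(**{**asdict(rhythm_cfg),
                               "n_permutations": cfg.n_rhythm_permutations})
    for ci, ch in enumerate(aligned.channels):
        x = aligned.feature_series(ci, band_idx)
        cr = wavelet_coherence(x, y, step_h, rhythm_cfg)
        sig = circadian_coherence_significance(x, y, step_h, perm_cfg, rngs["rhythm"])
        phase = circadian_phase_lag(cr, significant=sig["significant"])
        ult = ultradian_coupling(x, y, step_h, rhythm_cfg, cfg.coupling,
                                 masks=aligned.masks, rng=rngs["rhythm"],
                                 run_null=False)
        rhythm_rows.append({
            "channel": ch.name, "region": ch.region,
            "circadian_coherence": sig["circadian_coherence"],
            "coherence_p": sig["p"], "significant": sig["significant"],
            "phase_lag_h": phase,
            "ultradian_r": ult.r_at_best, "ultradian_lag_h": ult.best_lag_h,
            "ultradian_r_wake": ult.per_state.get("wake", np.nan),
            "ultradian_r_sleep": ult.per_state.get("sleep", np.nan),
            "best_lag_h": coupling_df.loc[ci, "best_lag_h"],
        })
    rhythm_df = pd.DataFrame(rhythm_rows)
    rhythm_df.to_csv(out / "rhythms.csv", index=False)
    manifest["stages"]["rhythms"] = {
        "elapsed_s": round(time.time() - timer, 2),
        "phase_vs_lag": phase_vs_temporal_lag(rhythm_df, min_channels=3),
    }

    # ---- decoder -----------------------------------------------------------
    timer = time.time()
    ft = build_features(aligned, target=cfg.target, cfg=cfg.decoder)
    if cfg.target == "level":
        ft.y, _ = saturate_target(ft.y, cfg.decoder.hyperglycemia_threshold)
    result = fit_lasso_lar(ft, cfg.decoder, rngs["decode"])
    result.nonzero.to_csv(out / "decoder_coefficients.csv", index=False)
    pd.DataFrame({"timestamp": ft.timestamps[result.test_rows],
                  "actual": result.y_test,
                  "predicted": result.predictions}).to_csv(
        out / "decoder_predictions.csv", index=False)
    rmse_df = stratified_rmse(result, aligned.masks, ft.row_indices)
    rmse_df.to_csv(out / "decoder_state_rmse.csv", index=False)
    decode_stage = {"elapsed_s": None, "alpha": result.alpha,
                    "test_r": result.test_r, "test_rmse": result.test_rmse,
                    "mean_cv_r": float(result.per_fold_r.mean()),
                    "split_mode": result.split_mode}

    if cfg.run_sweep:
        lo, hi, step = cfg.sweep_range_h
        sweep = shift_sweep(aligned, np.arange(lo, hi + step / 2, step),
                            cfg.decoder, target=cfg.target, seed=cfg.seed)
        pd.DataFrame({"shift_h": sweep.shifts_h, "mean_cv_r": sweep.mean_cv_r,
                      "sem_cv_r": sweep.sem_cv_r}).to_csv(out / "shift_sweep.csv",
                                                          index=False)
        decode_stage["best_shift_h"] = sweep.best_shift_h
        decode_stage["sweep_at_boundary"] = sweep.at_boundary
    if cfg.run_controls:
        controls = circadian_controls(aligned, cfg.decoder, rhythm_cfg, seed=cfg.seed)
        controls.to_csv(out / "decoder_controls.csv", index=False)
    if cfg.run_importance:
        imp = bootstrap_importance(ft, result.alpha, cfg.n_bootstrap, rngs["decode"])
        imp.to_csv(out / "decoder_importance.csv", index=False)
    decode_stage["elapsed_s"] = round(time.time() - timer, 2)
    manifest["stages"]["decoder"] = decode_stage

    # ---- report ------------------------------------------------------------
    summary = [
        f"neuroglyc {__version__} run (seed {cfg.seed}, config {cfg.config_hash()})",
        f"channels: {len(aligned.channels)}  grid points: {len(aligned)} "
        f"(valid {aligned.n_valid})",
        f"coupling: median best lag {coupling_df['best_lag_h'].median():+.2f} h, "
        f"median |r| {coupling_df['r'].abs().median():.3f}",
        f"rhythms: mean circadian coherence "
        f"{rhythm_df['circadian_coherence'].mean():.3f}, "
        f"mean phase lag {rhythm_df['phase_lag_h'].mean():+.2f} h",
        f"decoder ({result.split_mode} split): test R {result.test_r:.3f}, "
        f"RMSE {result.test_rmse:.2f} mg/dL, alpha {result.alpha:.4g}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")

    manifest["outputs"] = {p.name: _checksum(p) for p in sorted(out.glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def main() -> None:
    """Neural powerband ↔ interstitial glucose coupling analysis."""


def _cfg_from(config: str | None, seed: int, out: str) -> RunConfig:
    cfg = RunConfig.from_yaml(config) if config else RunConfig()
    cfg.seed = seed
    cfg.out_dir = out
    return cfg


@main.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="neuroglyc_run")
def simulate_cmd(config: str | None, seed: int, out: str) -> None:
    """Generate synthetic envelopes, glucose and annotations."""
    cfg = _cfg_from(config, seed, out)
    sim_cfg = SyntheticConfig(**{**asdict(cfg.synthetic), "seed": seed})
    envelopes, glucose, states, truth = simulate(sim_cfg)
    out_p = Path(out)
    out_p.mkdir(parents=True, exist_ok=True)
    write_glucose(out_p / "glucose.csv", glucose)
    write_annotations(out_p / "states.csv", states)
    write_features_csv(out_p / "features.csv", envelopes)
    (out_p / "ground_truth.json").write_text(json.dumps({
        "lag_h": truth.lag_h,
        "phase_offset_h": truth.phase_offset_h,
        "coupled": truth.coupled,
    }, default=str, indent=1))
    click.echo(f"wrote synthetic dataset to {out}")


main.add_command(simulate_cmd, name="simulate")


@main.command(name="run-all")
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="neuroglyc_run")
@click.option("--sweep/--no-sweep", default=False)
@click.option("--controls/--no-controls", default=False)
@click.option("--importance/--no-importance", default=False)
def run_all_cmd(config, seed, out, sweep, controls, importance) -> None:
    """Full pipeline: inputs → coupling → rhythms → decoder → report."""
    cfg = _cfg_from(config, seed, out)
    cfg.run_sweep = cfg.run_sweep or sweep
    cfg.run_controls = cfg.run_controls or controls
    cfg.run_importance = cfg.run_importance or importance
    manifest = run_all(cfg)
    click.echo((Path(out) / "summary.txt").read_text())
    click.echo(f"manifest: {Path(out) / 'manifest.json'} "
               f"(config {manifest['config_hash']})")


@main.command()
@click.option("--features", "features_path", type=click.Path(exists=True), required=True)
@click.option("--glucose", "glucose_path", type=click.Path(exists=True), required=True)
@click.option("--states", "states_path", type=click.Path(exists=True), default=None)
@click.option("--target", type=click.Choice(["level", "derivative"]), default="level")
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="neuroglyc_run")
def couple_cmd(features_path, glucose_path, states_path, target, seed, out) -> None:
    """Lag-resolved coupling of stored feature/glucose CSVs."""
    cfg = RunConfig(out_dir=out, seed=seed, glucose_path=glucose_path,
                    features_path=features_path, states_path=states_path,
                    target=target)
    run_all(cfg)
    click.echo((Path(out) / "summary.txt").read_text())


main.add_command(couple_cmd, name="couple")


@main.command(name="preprocess")
@click.option("--neural", "neural_path", type=click.Path(exists=True), required=True,
              help="EDF or matrix CSV (with JSON sidecar)")
@click.option("--out", type=click.Path(), default="neuroglyc_run")
def preprocess_cmd(neural_path, out) -> None:
    """Raw voltage → smoothed powerband envelope CSV."""
    from .io_timebase import read_neural
    from .spectral import compute_envelopes

    rec = read_neural(neural_path)
    env = compute_envelopes(rec)
    out_p = Path(out)
    out_p.mkdir(parents=True, exist_ok=True)
    write_features_csv(out_p / "features.csv", env)
    click.echo(f"wrote {out_p / 'features.csv'} "
               f"({len(env.channels)} channels × {len(env.bands)} bands)")


@main.command(name="rhythms")
@click.option("--features", "features_path", type=click.Path(exists=True), required=True)
@click.option("--glucose", "glucose_path", type=click.Path(exists=True), required=True)
@click.option("--states", "states_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="neuroglyc_run")
def rhythms_cmd(features_path, glucose_path, states_path, seed, out) -> None:
    """Wavelet coherence / circadian phase-lag tables for stored CSVs."""
    cfg = RunConfig(out_dir=out, seed=seed, glucose_path=glucose_path,
                    features_path=features_path, states_path=states_path)
    run_all(cfg)
    click.echo((Path(out) / "rhythms.csv").read_text())


@main.command(name="ccep")
@click.option("--neural", "neural_path", type=click.Path(exists=True), required=True)
@click.option("--pulses", "pulse_path", type=click.Path(exists=True), required=True,
              help="CSV with a pulse_time_s column")
@click.option("--out", type=click.Path(), default="neuroglyc_run")
def ccep_cmd(neural_path, pulse_path, out) -> None:
    """Epoch stimulation pulses and write per-channel evoked magnitudes."""
    from .ccep import epoch_and_baseline
    from .io_timebase import read_neural

    rec = read_neural(neural_path)
    pulses = pd.read_csv(pulse_path)["pulse_time_s"].to_numpy(dtype=float)
    eps = epoch_and_baseline(rec, pulses)
    mags = ccep_magnitude(eps)
    out_p = Path(out)
    out_p.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"channel": [c.name for c in rec.channels],
                       "n_epochs": eps.n_pulses, "magnitude_uv": mags})
    df.to_csv(out_p / "ccep_summary.csv", index=False)
    click.echo(df.to_string(index=False))


@main.command()
@click.option("--features", "features_path", type=click.Path(exists=True), required=True)
@click.option("--glucose", "glucose_path", type=click.Path(exists=True), required=True)
@click.option("--states", "states_path", type=click.Path(exists=True), default=None)
@click.option("--sweep-range", default="-6:6:0.5", help="lo:hi:step hours")
@click.option("--controls", is_flag=True)
@click.option("--importance", is_flag=True)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="neuroglyc_run")
def decode_cmd(features_path, glucose_path, states_path, sweep_range,
               controls, importance, seed, out) -> None:
    """Glucose decoder with optional shift sweep, controls and importance."""
    lo, hi, step = (float(v) for v in sweep_range.split(":"))
    cfg = RunConfig(out_dir=out, seed=seed, glucose_path=glucose_path,
                    features_path=features_path, states_path=states_path,
                    run_sweep=True, sweep_range_h=(lo, hi, step),
                    run_controls=controls, run_importance=importance)
    run_all(cfg)
    click.echo((Path(out) / "summary.txt").read_text())


main.add_command(decode_cmd, name="decode")


if __name__ == "__main__":
    main()
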