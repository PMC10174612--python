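"""Readers, writers and the shared timebase.

Neural recordings, CGM glucose series and behavioral-state annotations all
enter the analysis here.  The module also owns the alignment rules that put
neural feature series and glucose on one 5-min grid: every glucose timestamp
is matched to the nearest neural feature sample within a tolerance (default
±1 s), short CGM gaps (≤ 3 consecutive points) are linearly interpolated,
and the glucose rate of change is the backward first difference in
mg/dL per minute.

All timestamps are absolute (numpy ``datetime64``); time of day is derived
from them where circadian controls need it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REGION_VOCABULARY = (
    "hypothalamus",
    "insula",
    "cingulate",
    "ahc",
    "frontal",
    "temporal",
    "subcortical",
    "orbitofrontal",
    "unassigned",
)

STATE_LABELS = ("sleep", "wake", "pre_prandial", "prandial")

GLUCOSE_CADENCE_S = 300.0  # nominal CGM sampling interval
MAX_INTERP_GAP = 3  # longest run of missing CGM points that may be filled


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ChannelMeta:
    """Metadata for one recording contact."""

    name: str
    electrode: str = ""
    contact_index: int = 0
    region: str = "unassigned"
    tissue: str = "gray"  # gray | white | excluded
    laterality: str = "midline"  # left | right | midline

    def __post_init__(self) -> None:
        if self.region not in REGION_VOCABULARY:
            self.region = "unassigned"


@dataclass
class NeuralRecording:
    """Multichannel voltage matrix (µV) with sampling rate and channel metadata."""

    samples: np.ndarray  # channels × time
    fs: float
    start_time: np.datetime64
    channels: list[ChannelMeta]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels × time matrix")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel metadata must match number of rows")
        self.start_time = np.datetime64(self.start_time, "ns")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from the start of the recording."""
        return np.arange(self.n_samples) / self.fs

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + (self.times * 1e9).astype("timedelta64[ns]")


@dataclass
class GlucoseSeries:
    """Interstitial glucose on a regular (nominally 5-min) grid.

    Missing points are NaN with ``source_flag == "missing"``; points filled by
    :func:`interpolate_gaps` are flagged ``"interpolated"``.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    source_flag: np.ndarray
    cadence_s: float = GLUCOSE_CADENCE_S
    units: str = "mg/dL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.source_flag = np.asarray(self.source_flag, dtype=object)
        if not (len(self.timestamps) == len(self.values) == len(self.source_flag)):
            raise ValueError("timestamps, values and source_flag must align")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps.asi8) / 1e9
            if not np.all(dt > 0):
                raise ValueError("timestamps must be strictly increasing")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] <= 0) and self.units == "mg/dL":
            raise ValueError("glucose values must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def measured(self) -> np.ndarray:
        return self.source_flag == "measured"

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def gap_runs(self) -> list[tuple[int, int]]:
        """(start, length) of each run of consecutive missing points."""
        runs: list[tuple[int, int]] = []
        miss = self.missing
        i = 0
        n = len(miss)
        while i < n:
            if miss[i]:
                j = i
                while j < n and miss[j]:
                    j += 1
                runs.append((i, j - i))
                i = j
            else:
                i += 1
        return runs


@dataclass
class StateAnnotations:
    """Labeled behavioral intervals resolvable to boolean masks on any grid."""

    intervals: pd.DataFrame  # columns: start, end, label
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        df["start"] = pd.to_datetime(df["start"])
        df["end"] = pd.to_datetime(df["end"])
        if (df["end"] <= df["start"]).any():
            raise ValueError("interval end must follow start")
        bad = set(df["label"]) - set(STATE_LABELS)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        self.intervals = df.reset_index(drop=True)

    def mask(self, timestamps: pd.DatetimeIndex, label: str) -> np.ndarray:
        """Boolean vector: timestamp falls inside any interval with ``label``."""
        out = np.zeros(len(timestamps), dtype=bool)
        sel = self.intervals[self.intervals["label"] == label]
        ts = timestamps.asi8
        for _, row in sel.iterrows():
            out |= (ts >= row["start"].value) & (ts < row["end"].value)
        return out

    def masks(self, timestamps: pd.DatetimeIndex) -> dict[str, np.ndarray]:
        return {lab: self.mask(timestamps, lab) for lab in STATE_LABELS}

    @classmethod
    def from_schedule(
        cls,
        sleep_intervals: list[tuple[pd.Timestamp, pd.Timestamp]],
        meal_times: list[pd.Timestamp],
        span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
        provenance: str = "schedule",
    ) -> "StateAnnotations":
        """Build annotations from sleep intervals and meal start times.

        Pre-prandial spans −3→0 h and prandial 0→3 h around each meal start.
        Wake intervals are the complement of sleep over ``span``.
        """
        rows = []
        for s, e in sleep_intervals:
            rows.append({"start": s, "end": e, "label": "sleep"})
        for m in meal_times:
            m = pd.Timestamp(m)
            rows.append({"start": m - pd.Timedelta(hours=3), "end": m, "label": "pre_prandial"})
            rows.append({"start": m, "end": m + pd.Timedelta(hours=3), "label": "prandial"})
        if span is not None:
            lo, hi = pd.Timestamp(span[0]), pd.Timestamp(span[1])
            edges = sorted((pd.Timestamp(s), pd.Timestamp(e)) for s, e in sleep_intervals)
            cursor = lo
            for s, e in edges:
                if s > cursor:
                    rows.append({"start": cursor, "end": min(s, hi), "label": "wake"})
                cursor = max(cursor, e)
            if cursor < hi:
                rows.append({"start": cursor, "end": hi, "label": "wake"})
        return cls(pd.DataFrame(rows, columns=["start", "end", "label"]), provenance)


@dataclass
class AlignedPair:
    """Neural feature series and glucose on the shared 5-min grid.

    The grid stays regular: glucose points with no neural match inside the
    tolerance are not physically removed but invalidated on *both* sides
    (NaN + ``valid == False``), so downstream lag arithmetic can use row
    offsets while correlations exclude invalid samples pairwise.
    """

    grid: pd.DatetimeIndex
    neural: np.ndarray  # channels × bands × time
    glucose: np.ndarray  # time
    valid: np.ndarray  # time, bool
    masks: dict[str, np.ndarray]
    channels: list[ChannelMeta]
    bands: list[str]
    cadence_s: float = GLUCOSE_CADENCE_S

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def feature_series(self, channel: int, band: int) -> np.ndarray:
        """One channel/band series with invalid samples as NaN."""
        x = self.neural[channel, band].copy()
        x[~self.valid] = np.nan
        return x

    def glucose_series(self) -> np.ndarray:
        y = self.glucose.copy()
        y[~self.valid] = np.nan
        return y


# ---------------------------------------------------------------------------
# neural I/O
# ---------------------------------------------------------------------------


def _write_edf(path: Path, rec: NeuralRecording) -> None:
    """Minimal continuous 16-bit EDF writer (1-s data records).

    Supports only what the package itself needs to round-trip synthetic
    recordings; anatomical metadata does not fit EDF and travels in the
    JSON sidecar written by :func:`write_neural`.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_per_rec = fs
    n_records = int(np.ceil(rec.n_samples / n_per_rec))
    nchan = rec.n_channels
    data = np.full((nchan, n_records * n_per_rec), np.nan)
    data[:, : rec.n_samples] = rec.samples
    data[:, rec.n_samples:] = 0.0

    phys_min = np.nanmin(data, axis=1)
    phys_max = np.nanmax(data, axis=1)
    span = phys_max - phys_min
    flat = span <= 0
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    start = pd.Timestamp(rec.start_time)
    header = "".join(
        [
            "0".ljust(8),
            "X X X X".ljust(80),
            "Startdate X X X X".ljust(80),
            start.strftime("%d.%m.%y"),
            start.strftime("%H.%M.%S"),
            str(256 * (1 + nchan)).ljust(8),
            "".ljust(44),
            str(n_records).ljust(8),
            "1".ljust(8),
            str(nchan).ljust(4),
        ]
    )

    def fields(values, width):
        return "".join(str(v).ljust(width)[:width] for v in values)

    labels = [c.name[:16] for c in rec.channels]
    header += fields(labels, 16)
    header += fields(["sEEG"] * nchan, 80)
    header += fields(["uV"] * nchan, 8)
    header += fields([f"{v:.6g}" for v in phys_min], 8)
    header += fields([f"{v:.6g}" for v in phys_max], 8)
    header += fields([dig_min] * nchan, 8)
    header += fields([dig_max] * nchan, 8)
    header += fields([""] * nchan, 80)
    header += fields([n_per_rec] * nchan, 8)
    header += fields([""] * nchan, 32)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for r in range(n_records):
            chunk = data[:, r * n_per_rec : (r + 1) * n_per_rec]
            dig = np.round((chunk - phys_min[:, None]) * scale[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())


def _edf_samples_per_record(path: Path) -> list[int]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        nchan = int(head[252:256].decode("ascii").strip())
        fh.seek(256 + nchan * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80))
        raw = fh.read(nchan * 8)
    return [int(raw[i * 8 : (i + 1) * 8].decode("ascii").strip()) for i in range(nchan)]


def write_neural(path: str | Path, rec: NeuralRecording, format: str = "edf") -> None:
    """Write a recording as EDF or as a numeric matrix, plus a JSON sidecar."""
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "start_time": str(pd.Timestamp(rec.start_time)),
        "channels": [vars(c) for c in rec.channels],
    }
    if format == "edf":
        _write_edf(path, rec)
    elif format == "matrix":
        df = pd.DataFrame(rec.samples.T, columns=[c.name for c in rec.channels])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown neural format: {format}")
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_neural(path: str | Path, format: str = "auto") -> NeuralRecording:
    """Read an EDF or numeric-matrix recording into a :class:`NeuralRecording`.

    A JSON sidecar (``<path>.json``) supplies anatomical channel metadata;
    channels without sidecar entries get region ``"unassigned"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"

    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    by_name = {c["name"]: c for c in meta.get("channels", [])}

    if format == "edf":
        rates = _edf_samples_per_record(path)
        if len(set(rates)) > 1:
            raise ValueError("EDF with mismatched per-channel sampling rates")
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        samples = raw.get_data() * 1e6  # mne returns volts
        fs = float(raw.info["sfreq"])
        meas = raw.info.get("meas_date")
        start = np.datetime64(meas.replace(tzinfo=None)) if meas else np.datetime64("2000-01-01")
        names = raw.ch_names
    elif format == "matrix":
        df = pd.read_csv(path)
        samples = df.to_numpy(dtype=float).T
        names = list(df.columns)
        if "fs" not in meta:
            raise ValueError("matrix format requires a JSON sidecar with fs")
        fs = float(meta["fs"])
        start = np.datetime64(meta.get("start_time", "2000-01-01"))
    else:
        raise ValueError(f"unknown neural format: {format}")

    if "start_time" in meta:
        start = np.datetime64(pd.Timestamp(meta["start_time"]))
    channels = []
    for i, name in enumerate(names):
        info = by_name.get(name, {})
        channels.append(
            ChannelMeta(
                name=name,
                electrode=info.get("electrode", name.rstrip("0123456789") or name),
                contact_index=info.get("contact_index", i),
                region=info.get("region", "unassigned"),
                tissue=info.get("tissue", "gray"),
                laterality=info.get("laterality", "midline"),
            )
        )
    return NeuralRecording(samples=samples, fs=fs, start_time=start, channels=channels)


# ---------------------------------------------------------------------------
# glucose I/O and rules
# ---------------------------------------------------------------------------


def write_glucose(path: str | Path, g: GlucoseSeries) -> None:
    df = pd.DataFrame({"timestamp": g.timestamps, "glucose_mg_dl": g.values})
    df = df[np.isfinite(g.values)]
    df.to_csv(path, index=False)


def read_glucose(
    path: str | Path, cadence_s: float = GLUCOSE_CADENCE_S, tolerance_frac: float = 0.2
) -> GlucoseSeries:
    """Read a two-column CGM CSV (timestamp, mg/dL) onto the nominal grid.

    Extra vendor columns are ignored.  Timestamps must be strictly
    increasing; values must be positive.  Points are snapped to the regular
    cadence grid anchored at the first sample; grid points with no
    measurement become missing (NaN) and are later handled by
    :func:`interpolate_gaps`.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    tcol = next((cols[k] for k in ("timestamp", "time", "datetime") if k in cols), df.columns[0])
    vcol = next(
        (cols[k] for k in ("glucose_mg_dl", "glucose", "mg_dl", "value") if k in cols),
        df.columns[1],
    )
    ts = pd.to_datetime(df[tcol])
    vals = df[vcol].to_numpy(dtype=float)
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("glucose timestamps must be strictly increasing")
    if np.any(vals <= 0):
        raise ValueError("glucose values must be positive")

    t0 = ts.iloc[0]
    offs = (ts - t0).dt.total_seconds().to_numpy()
    idx = np.round(offs / cadence_s).astype(int)
    if np.any(np.abs(offs - idx * cadence_s) > tolerance_frac * cadence_s):
        raise ValueError("glucose cadence deviates beyond tolerance from nominal grid")
    n = idx[-1] + 1
    values = np.full(n, np.nan)
    flags = np.full(n, "missing", dtype=object)
    values[idx] = vals
    flags[idx] = "measured"
    grid = pd.date_range(t0, periods=n, freq=pd.Timedelta(seconds=cadence_s))
    return GlucoseSeries(timestamps=grid, values=values, source_flag=flags, cadence_s=cadence_s)


def interpolate_gaps(g: GlucoseSeries, max_gap: int = MAX_INTERP_GAP) -> GlucoseSeries:
    """Fill gaps of at most ``max_gap`` consecutive points linearly.

    Longer gaps are left missing and excluded from all downstream analyses.
    Measured points are never modified; the operation is idempotent.
    """
    values = g.values.copy()
    flags = g.source_flag.copy()
    for start, length in g.gap_runs():
        if length > max_gap:
            continue
        lo, hi = start - 1, start + length
        if lo < 0 or hi >= len(values):
            continue  # gap touches an edge: no flanking pair to bridge
        if not (np.isfinite(values[lo]) and np.isfinite(values[hi])):
            continue
        frac = np.arange(1, length + 1) / (length + 1)
        values[start : start + length] = values[lo] + frac * (values[hi] - values[lo])
        flags[start : start + length] = "interpolated"
    return GlucoseSeries(g.timestamps, values, flags, g.cadence_s, g.units)


def glucose_derivative(g: GlucoseSeries) -> GlucoseSeries:
    """Backward first difference in mg/dL per minute, stamped at the later point."""
    dt = np.diff(g.timestamps.asi8) / 1e9
    if len(dt) == 0:
        raise ValueError("need at least two points for a derivative")
    if np.ptp(dt) > 1e-6:
        raise ValueError("derivative requires a uniform cadence")
    step_min = dt[0] / 60.0
    dv = np.diff(g.values) / step_min
    flags = np.where(
        ~np.isfinite(dv),
        "missing",
        np.where((g.source_flag[:-1] == "measured") & (g.source_flag[1:] == "measured"),
                 "measured", "interpolated"),
    ).astype(object)
    return GlucoseSeries(g.timestamps[1:], dv, flags, g.cadence_s, units="mg/dL/min")


# ---------------------------------------------------------------------------
# annotations I/O
# ---------------------------------------------------------------------------


def write_annotations(path: str | Path, states: StateAnnotations) -> None:
    states.intervals.to_csv(path, index=False)


def read_annotations(path: str | Path) -> StateAnnotations:
    df = pd.read_csv(path)
    return StateAnnotations(df[["start", "end", "label"]], provenance=str(path))


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align(
    envelopes,
    g: GlucoseSeries,
    states: StateAnnotations | None = None,
    tolerance_s: float = 1.0,
    min_match_frac: float = 0.5,
) -> AlignedPair:
    """Match each glucose timestamp to the nearest neural feature sample.

    ``envelopes`` is any object exposing ``timestamps`` (DatetimeIndex),
    ``values`` (channels × bands × time), ``channels`` and ``bands`` — in
    practice a :class:`neuroglyc.spectral.PowerbandEnvelope`.  A glucose
    point whose nearest envelope sample lies beyond ``tolerance_s`` is
    invalidated on both sides.  Fewer than ``min_match_frac`` matchable
    points raises (clock misalignment).
    """
    env_t = np.asarray(pd.DatetimeIndex(envelopes.timestamps).asi8, dtype=np.int64)
    glu_t = g.timestamps.asi8
    vals = np.asarray(envelopes.values, dtype=float)
    if vals.ndim != 3:
        raise ValueError("envelope values must be channels × bands × time")

    pos = np.searchsorted(env_t, glu_t)
    pos = np.clip(pos, 1, len(env_t) - 1)
    left, right = env_t[pos - 1], env_t[pos]
    take_left = (glu_t - left) <= (right - glu_t)
    nearest = np.where(take_left, pos - 1, pos)
    dt_s = np.abs(glu_t - env_t[nearest]) / 1e9
    matched = dt_s <= tolerance_s
    if matched.mean() < min_match_frac:
        raise ValueError(
            f"only {matched.mean():.0%} of glucose points matchable within "
            f"±{tolerance_s} s — check clock alignment"
        )

    neural = vals[:, :, nearest]
    env_ok = np.isfinite(neural).all(axis=(0, 1))
    valid = matched & env_ok & np.isfinite(g.values)
    neural[:, :, ~valid] = np.nan
    glucose = g.values.copy()
    glucose[~valid] = np.nan

    masks = states.masks(g.timestamps) if states is not None else {}
    return AlignedPair(
        grid=g.timestamps,
        neural=neural,
        glucose=glucose,
        valid=valid,
        masks=masks,
        channels=list(envelopes.channels),
        bands=list(envelopes.bands),
        cadence_s=g.cadence_s,
    )
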