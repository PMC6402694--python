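"""Data model and file formats for delay-period trial tables.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per trial: task metadata columns (:data:`METADATA_COLUMNS`) followed by one
column per recorded channel (``rate_000`` ... ``rate_095`` by default) holding
the delay-window firing rate in spikes/s.  CSV is the interchange format;
per-trial rate *time series* live in an HDF5 container (see
:class:`RateTimeSeries`).

Units: positions in cm (origin at the central touch point), speeds in cm/s,
times in ms, angles in radians internally (reports print degrees).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

TASKS = ("ring", "horizontal", "vertical", "rings3")
SUBJECTS = ("J", "R")

#: Required metadata columns, in canonical order.
METADATA_COLUMNS = [
    "trial_id",
    "session_id",
    "task",
    "condition_id",
    "target_x",
    "target_y",
    "delay",
    "max_speed",
    "max_speed_x",
    "max_speed_y",
]


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class FormatError(ValueError):
    """Unknown file format."""


class ValidationError(ValueError):
    """Table contents violate a TrialTable invariant."""


def rate_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-channel rate columns, in channel order."""
    cols = sorted(c for c in table.columns if c.startswith("rate_"))
    return cols


def rate_matrix(table: pd.DataFrame) -> np.ndarray:
    """Trials x channels array of firing rates (float64)."""
    return table[rate_columns(table)].to_numpy(dtype=float)


def set_rate_matrix(table: pd.DataFrame, rates: np.ndarray) -> pd.DataFrame:
    """Return a copy of *table* with its rate columns replaced by *rates*."""
    out = table.copy()
    out[rate_columns(table)] = rates
    return out


def rate_column_names(n_channels: int) -> list[str]:
    return [f"rate_{ch:03d}" for ch in range(n_channels)]


def target_distances(table: pd.DataFrame, decimals: int = 6) -> np.ndarray:
    """Per-trial target distance from the origin, rounded to 1e-6 cm.

    Rounding makes 'per distance' grouping robust to floating noise in
    target coordinates.
    """
    d = np.hypot(table["target_x"].to_numpy(float), table["target_y"].to_numpy(float))
    return np.round(d, decimals)


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Check TrialTable invariants; return the table unchanged.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for non-finite rates, non-positive delays or a
    condition id that maps to more than one target within a task.
    """
    for col in METADATA_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"missing required column {col!r}")
    rcols = rate_columns(table)
    if not rcols:
        raise SchemaError("missing rate columns (rate_000, ...)")
    rates = table[rcols].to_numpy(dtype=float)
    bad = ~np.isfinite(rates)
    if bad.any():
        row = int(np.nonzero(bad.any(axis=1))[0][0])
        tid = table["trial_id"].iloc[row]
        raise ValidationError(f"non-finite rate in trial_id {tid}")
    if (table["delay"] <= 0).any():
        tid = table.loc[table["delay"] <= 0, "trial_id"].iloc[0]
        raise ValidationError(f"non-positive delay in trial_id {tid}")
    uniq = table.groupby(["task", "condition_id"])[["target_x", "target_y"]].nunique()
    if (uniq > 1).any().any():
        raise ValidationError("a condition_id maps to multiple targets within a task")
    return table


def write_trials(table: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Write a TrialTable; lossless roundtrip through :func:`read_trials`."""
    path = Path(path)
    validate_trials(table)
    cols = METADATA_COLUMNS + rate_columns(table)
    if format == "csv":
        table[cols].to_csv(path, index=False)
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            for col in cols:
                vals = table[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype(str)
                    f.create_dataset(f"trials/{col}", data=vals.astype("S"))
                else:
                    f.create_dataset(f"trials/{col}", data=vals)
            f.attrs["columns"] = json.dumps(cols)
    else:
        raise FormatError(f"unknown format {format!r}")
    return path


def read_trials(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read a TrialTable written by :func:`write_trials`; row order preserved."""
    path = Path(path)
    if format == "csv":
        table = pd.read_csv(
            path, dtype={"session_id": str, "task": str}, float_precision="round_trip"
        )
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            cols = json.loads(f.attrs["columns"])
            data = {}
            for col in cols:
                vals = f[f"trials/{col}"][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                data[col] = vals
        table = pd.DataFrame(data, columns=cols)
    else:
        raise FormatError(f"unknown format {format!r}")
    return validate_trials(table)


@dataclasses.dataclass
class RateTimeSeries:
    """Per-trial rate time series around target onset.

    Attributes
    ----------
    rates : (n_trials, n_channels, n_timesteps) array, spikes/s
    time_ms : (n_timesteps,) uniform time axis, ms relative to target onset
    go_cue_ms : per-trial go-cue time (ms relative to target onset)
    meta : trial metadata frame (METADATA_COLUMNS sans rates)
    """

    rates: np.ndarray
    time_ms: np.ndarray
    go_cue_ms: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.go_cue_ms = np.atleast_1d(np.asarray(self.go_cue_ms, dtype=float))
        if self.go_cue_ms.size == 1:
            self.go_cue_ms = np.full(self.rates.shape[0], self.go_cue_ms[0])
        dt = np.diff(self.time_ms)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValidationError("time axis must be uniform")
        inside = (self.go_cue_ms >= self.time_ms[0]) & (self.go_cue_ms <= self.time_ms[-1])
        if not inside.all():
            raise ValidationError("go-cue time outside the recorded series")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.rates.shape[1]


def write_timecourse(series: RateTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=series.rates)
        f.create_dataset("time_ms", data=series.time_ms)
        f.create_dataset("go_cue_ms", data=series.go_cue_ms)
        for col in series.meta.columns:
            vals = series.meta[col].to_numpy()
            if vals.dtype == object:
                f.create_dataset(f"meta/{col}", data=vals.astype(str).astype("S"))
            else:
                f.create_dataset(f"meta/{col}", data=vals)
        f.attrs["meta_columns"] = json.dumps(list(series.meta.columns))
    return path


def read_timecourse(path: str | Path) -> RateTimeSeries:
    path = Path(path)
    with h5py.File(path, "r") as f:
        rates = f["rates"][()]
        time_ms = f["time_ms"][()]
        go_cue = f["go_cue_ms"][()]
        cols = json.loads(f.attrs["meta_columns"])
        data = {}
        for col in cols:
            vals = f[f"meta/{col}"][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            data[col] = vals
    meta = pd.DataFrame(data, columns=cols)
    return RateTimeSeries(rates=rates, time_ms=time_ms, go_cue_ms=go_cue, meta=meta)


@dataclasses.dataclass
class RunConfig:
    """Flat pipeline configuration (YAML/JSON on disk)."""

    window_lo: float = -200.0  # ms relative to go cue, exclusive
    window_hi: float = 0.0  # ms relative to go cue, inclusive
    variance_threshold: float = 0.95
    folds: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance threshold must be in (0, 1]")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if not self.window_hi > self.window_lo:
            raise ValueError("window length must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset covers JSON
        return cls(**data)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
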