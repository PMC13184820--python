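"""Data model and serialization for traces, event boundaries, and feature tables.

A :class:`Trace` is a uniformly sampled ionic-current time series (pA) with
acquisition metadata. On disk a trace is a raw little-endian float64 binary
file plus a JSON sidecar (``<name>.json``) carrying sampling rate, voltage and
free-form metadata; a plain CSV (one sample per line) is accepted on read as a
fallback. Event-boundary tables and per-event feature tables are CSV.

Conventions: event boundaries are 0-based, half-open ``[start, end)`` sample
indices; missing feature values are empty CSV cells (NaN in memory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "EventBoundaryTable",
    "FormatError",
    "ValidationError",
    "read_trace",
    "write_trace",
    "read_event_boundaries",
    "write_event_boundaries",
    "read_feature_table",
    "write_feature_table",
]


class FormatError(ValueError):
    """A file does not conform to the documented interchange format."""


class ValidationError(ValueError):
    """Input values violate a structural invariant."""


@dataclass
class Trace:
    """A single-channel current recording.

    Parameters
    ----------
    samples : array of float
        Current samples in pA.
    sampling_rate : float
        Acquisition rate in Hz (e.g. 50 000).
    voltage : float
        Applied trans-side potential in mV (cis grounded).
    metadata : dict
        Free-form acquisition metadata (electrolyte, pore variant, analyte...).
    """

    samples: np.ndarray
    sampling_rate: float
    voltage: float = 100.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if not (self.sampling_rate > 0):
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sampling_rate

    def __len__(self) -> int:
        return self.samples.size


class EventBoundaryTable:
    """Sorted, non-overlapping half-open event boundaries with optional labels."""

    def __init__(self, start, end, label=None, n_samples: int | None = None):
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if start.shape != end.shape:
            raise ValidationError("start and end must have equal length")
        if label is None:
            label = np.array([""] * start.size, dtype=object)
        else:
            label = np.asarray(label, dtype=object)
            if label.shape != start.shape:
                raise ValidationError("label length mismatch")
        order = np.argsort(start, kind="stable")
        start, end, label = start[order], end[order], label[order]
        bad = np.nonzero(end <= start)[0]
        if bad.size:
            raise ValidationError(f"end <= start in rows {bad.tolist()}")
        if start.size and start[0] < 0:
            raise ValidationError("negative start index")
        if n_samples is not None and start.size and end[-1] > n_samples:
            rows = np.nonzero(end > n_samples)[0]
            raise ValidationError(f"boundaries beyond trace length in rows {rows.tolist()}")
        overlap = np.nonzero(start[1:] < end[:-1])[0]
        if overlap.size:
            raise ValidationError(f"overlapping rows at positions {(overlap + 1).tolist()}")
        self.start = start
        self.end = end
        self.label = label

    def __len__(self) -> int:
        return self.start.size

    def __iter__(self):
        return iter(zip(self.start, self.end, self.label))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_sample": self.start, "end_sample": self.end, "label": self.label}
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventBoundaryTable)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
            and np.array_equal(self.label, other.label)
        )


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path) -> None:
    """Write a trace as raw little-endian float64 + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.samples.astype("<f8").tofile(path)
    sidecar = {
        "sampling_rate": trace.sampling_rate,
        "voltage": trace.voltage,
        "n_samples": int(trace.samples.size),
        "dtype": "<f8",
        "units": "pA",
        "metadata": trace.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path, sampling_rate: float | None = None, voltage: float = 100.0) -> Trace:
    """Read a trace from binary+sidecar, or from a one-column CSV fallback.

    For the CSV fallback no sidecar is required but ``sampling_rate`` must be
    given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such trace file: {path}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if path.suffix.lower() in {".csv", ".txt"} and not sidecar_path.exists():
        if sampling_rate is None:
            raise FormatError("CSV trace requires an explicit sampling_rate")
        samples = np.loadtxt(path, dtype=np.float64, ndmin=1)
        return Trace(samples, sampling_rate, voltage)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate", "n_samples"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field '{key}'")
    if not (float(meta["sampling_rate"]) > 0):
        raise FormatError(f"sidecar field 'sampling_rate' must be > 0, got {meta['sampling_rate']}")
    samples = np.fromfile(path, dtype=meta.get("dtype", "<f8"))
    if samples.size != int(meta["n_samples"]):
        raise FormatError(
            f"field 'n_samples' ({meta['n_samples']}) does not match file ({samples.size})"
        )
    if not np.all(np.isfinite(samples)):
        raise FormatError("field 'samples' contains non-finite values")
    return Trace(
        samples,
        float(meta["sampling_rate"]),
        float(meta.get("voltage", voltage)),
        dict(meta.get("metadata", {})),
    )


# ---------------------------------------------------------------------------
# Event boundary I/O
# ---------------------------------------------------------------------------

def write_event_boundaries(table: EventBoundaryTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False)


def read_event_boundaries(path, trace: Trace) -> EventBoundaryTable:
    """Read an event-boundary CSV against a trace.

    Accepts either sample-index columns (``start_sample``, ``end_sample``) or
    time columns in ms (``start_ms``, ``end_ms``, as exported by event-picking
    programs); times are converted via the trace sampling rate, rounding the
    start down and the end up. Output is validated and sorted.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"start_sample", "end_sample"} <= cols:
        start = df["start_sample"].to_numpy()
        end = df["end_sample"].to_numpy()
    elif {"start_ms", "end_ms"} <= cols:
        fs = trace.sampling_rate
        start = np.floor(df["start_ms"].to_numpy() * fs / 1000.0).astype(np.int64)
        end = np.ceil(df["end_ms"].to_numpy() * fs / 1000.0).astype(np.int64)
    else:
        raise FormatError(
            "boundary CSV needs columns (start_sample, end_sample) or (start_ms, end_ms); "
            f"got {sorted(cols)}"
        )
    label = df["label"].fillna("").to_numpy(dtype=object) if "label" in cols else None
    return EventBoundaryTable(start, end, label, n_samples=len(trace))


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

#: Canonical feature order; imported by the features module.
FEATURE_COLUMNS = [
    "dwell_time",
    "mean",
    "median",
    "std",
    "skew",
    "kurt",
    "delta_ratio",
    "blockade_charge",
    "rise_time",
    "fall_time",
    "fwhm",
    "spectral_centroid",
    "bp_low",
    "bp_mid",
    "bp_high",
    "spectral_entropy",
    "approx_entropy",
    "spike_count",
    "spike_rate",
]

_EXTRA_COLUMNS = ["label", "excluded", "exclusion_reason"]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a per-event feature table; missing values become empty cells."""
    out = table.copy()
    for col in FEATURE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    for col in _EXTRA_COLUMNS:
        if col not in out.columns:
            out[col] = "" if col != "excluded" else False
    out = out[FEATURE_COLUMNS + _EXTRA_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table; empty cells become NaN (the MISSING marker)."""
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in FEATURE_COLUMNS + _EXTRA_COLUMNS]
    if unknown:
        raise FormatError(f"unknown feature-table columns: {unknown}")
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"feature-table missing column '{col}'")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "label" in df.columns:
        df["label"] = df["label"].fillna("").astype(str)
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].fillna(False).astype(bool)
    if "exclusion_reason" in df.columns:
        df["exclusion_reason"] = df["exclusion_reason"].fillna("none").replace("", "none")
    return df
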