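"""Reading, validation and partitioning of RFID detection streams.

A detection stream is the raw observable of a feeder-based social study:
one row per PIT-tag read, carrying a timestamp, the individual's tag id,
the antenna that read it and the feeder location the antenna belongs to.
Internally timestamps are float seconds measured from a stream epoch
(a calendar timestamp), which keeps the association detectors free of
calendar arithmetic while still allowing calendar-aware weekly splits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DetectionStream",
    "ValidationReport",
    "read_detections",
    "write_detections",
    "validate_stream",
    "map_antennas_to_locations",
    "split_by_period",
]

#: canonical column order of the internal frame and the canonical CSV
CANONICAL_COLUMNS = ("time", "individual", "antenna", "location")

DEFAULT_SCHEMA = {c: c for c in CANONICAL_COLUMNS}

#: epoch used when input timestamps are already numeric seconds
_NUMERIC_EPOCH = pd.Timestamp("1970-01-01 00:00:00")


@dataclass
class DetectionStream:
    """Ordered PIT-tag reads at one or more feeder locations.

    Parameters
    ----------
    df
        Frame with columns ``time`` (float seconds from `epoch`, sorted
        non-decreasing), ``individual``, ``antenna``, ``location`` (str).
    epoch
        Calendar timestamp corresponding to ``time == 0``.
    metadata
        Free-form provenance (system name, hardware read interval, ...).
    """

    df: pd.DataFrame
    epoch: pd.Timestamp = _NUMERIC_EPOCH
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"stream frame missing columns: {missing}")
        t = self.df["time"].to_numpy()
        if len(t) and (not np.all(np.isfinite(t)) or t.min() < 0):
            raise ValueError("detection times must be finite and >= 0")
        if len(t) and np.any(np.diff(t) < 0):
            self.df = self.df.sort_values("time", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.df["individual"].unique())

    @property
    def locations(self) -> list[str]:
        return sorted(self.df["location"].unique())

    @property
    def span(self) -> float:
        t = self.times
        return float(t[-1] - t[0]) if len(t) else 0.0

    def timestamps(self) -> pd.Series:
        """Absolute calendar timestamps of every detection."""
        return self.epoch + pd.to_timedelta(self.df["time"], unit="s")

    def replace(self, **kw) -> "DetectionStream":
        return dataclasses.replace(self, **kw)


@dataclass
class ValidationReport:
    n_detections: int
    n_individuals: int
    n_locations: int
    span: float
    issues: list[tuple[str, str, int]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _parse_times(raw: pd.Series) -> tuple[np.ndarray, pd.Timestamp]:
    """Parse a timestamp column into (seconds-from-epoch, epoch).

    Numeric values are taken as epoch seconds with epoch 1970-01-01;
    anything else is parsed as ISO-8601 and rebased to the earliest read.
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float), _NUMERIC_EPOCH
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & numeric.isna()
    if not bad.any() and parsed.isna().any():
        bad = parsed.isna()  # mixed numeric/ISO column: treat as unparseable
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp at row {row}: {raw.iloc[row]!r} "
            "(expected epoch seconds or ISO-8601)"
        )
    epoch = parsed.min().floor("D")
    seconds = (parsed - epoch).dt.total_seconds().to_numpy(dtype=float)
    return seconds, epoch


def read_detections(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
) -> DetectionStream:
    """Read a delimited detection file into a sorted, deduplicated stream.

    ``schema`` maps the canonical names (time, individual, antenna,
    location) to the file's column names. Exact duplicate rows are
    collapsed; near-duplicates (same bird re-read within the hardware
    interval) are retained — the association detectors decide how to
    treat them.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    missing_keys = [k for k in CANONICAL_COLUMNS if k not in schema]
    if missing_keys:
        raise ValueError(f"schema must name columns for: {missing_keys}")
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if schema["time"] == "time" and "time" not in raw.columns \
            and "time_s" in raw.columns:
        schema["time"] = "time_s"  # canonical CSV header
    absent = [schema[k] for k in CANONICAL_COLUMNS if schema[k] not in raw.columns]
    if absent:
        raise ValueError(f"input file {path} missing columns: {absent}")
    df = raw[[schema[k] for k in CANONICAL_COLUMNS]].copy()
    df.columns = list(CANONICAL_COLUMNS)
    times, epoch = _parse_times(df["time"])
    df["time"] = times
    for c in ("individual", "antenna", "location"):
        df[c] = df[c].astype(str)
        if (df[c].str.len() == 0).any():
            raise ValueError(f"empty identifier in column {c!r}")
    df = df.drop_duplicates().sort_values("time", kind="stable").reset_index(drop=True)
    return DetectionStream(df=df, epoch=epoch, metadata={"source": str(path)})


def write_detections(stream: DetectionStream, path: str | Path) -> Path:
    """Write the canonical detections CSV (time_s, individual, antenna, location)."""
    out = stream.df.rename(columns={"time": "time_s"})
    path = Path(path)
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def validate_stream(stream: DetectionStream) -> ValidationReport:
    """Summarize a stream and flag structural oddities; never raises."""
    df = stream.df
    issues: list[tuple[str, str, int]] = []
    if len(df):
        neg = int((np.diff(stream.times) < 0).sum())
        if neg:  # impossible after the sort in __post_init__, kept as a tripwire
            issues.append(("negative_gap", "time goes backwards", neg))
        once = df["individual"].value_counts()
        n_once = int((once == 1).sum())
        if n_once:
            issues.append(("singleton_individual", "individuals seen exactly once", n_once))
        per_loc = df.groupby("location")["individual"].nunique()
        lonely = int((per_loc < 2).sum())
        if lonely:
            issues.append(("sparse_location", "locations with <2 individuals", lonely))
    return ValidationReport(
        n_detections=len(df),
        n_individuals=df["individual"].nunique() if len(df) else 0,
        n_locations=df["location"].nunique() if len(df) else 0,
        span=stream.span,
        issues=issues,
    )


def map_antennas_to_locations(
    stream: DetectionStream, mapping: Mapping[str, str]
) -> DetectionStream:
    """Rewrite the location field from an antenna->location table.

    Used for feeder architectures where several antennas (e.g. four
    adjacent perches) constitute one social location: birds read on any
    of them are feeding at the same place.
    """
    antennas = set(stream.df["antenna"].unique())
    unmapped = sorted(antennas - set(mapping))
    if unmapped:
        raise KeyError(f"antennas without a location mapping: {unmapped}")
    df = stream.df.copy()
    df["location"] = df["antenna"].map(mapping)
    return stream.replace(df=df)


def split_by_period(
    stream: DetectionStream,
    period: str = "week",
    boundary: Mapping[str, int] | None = None,
) -> list[tuple[str, DetectionStream]]:
    """Partition a stream into calendar periods (weekly sub-streams).

    ``period`` is "week" (ISO weeks by default) or "day". ``boundary``
    optionally shifts the block edge, e.g. ``{"weekday_start": 5,
    "hour_start": 4}`` starts each week block Saturday 04:00 (recording
    blocks that begin pre-dawn Saturday). Sub-streams keep the parent
    epoch, so they partition the input exactly.
    """
    if period not in ("week", "day"):
        raise ValueError("period must be 'week' or 'day'")
    if len(stream) == 0:
        return []
    ts = stream.timestamps()
    if boundary:
        shift = pd.Timedelta(hours=int(boundary.get("hour_start", 0)))
        wd = int(boundary.get("weekday_start", 0))
        ts = ts - shift - pd.Timedelta(days=wd)
    if period == "day":
        labels = ts.dt.strftime("%Y-%m-%d")
    else:
        iso = ts.dt.isocalendar()
        labels = iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    out: list[tuple[str, DetectionStream]] = []
    for label, sub in stream.df.groupby(labels.to_numpy(), sort=True):
        out.append(
            (str(label), stream.replace(df=sub.reset_index(drop=True)))
        )
    return out


def concat_streams(streams: Iterable[DetectionStream]) -> DetectionStream:
    """Concatenate streams sharing an epoch into one sorted stream."""
    streams = list(streams)
    if not streams:
        return DetectionStream(df=pd.DataFrame(columns=list(CANONICAL_COLUMNS)))
    epochs = {s.epoch for s in streams}
    if len(epochs) > 1:
        raise ValueError("cannot concatenate streams with different epochs")
    df = (
        pd.concat([s.df for s in streams], ignore_index=True)
        .sort_values("time", kind="stable")
        .reset_index(drop=True)
    )
    return DetectionStream(df=df, epoch=streams[0].epoch)
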