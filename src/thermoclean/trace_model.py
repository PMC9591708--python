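"""Core domain types and delimited-text I/O for temperature traces.

A trace is one surgical case's time-ordered temperature readings; times are
real-valued minutes relative to the case's first reading. Readers accept
either raw minute values or ISO-8601 timestamps (converted per case to
minutes from the first reading).

Canonical file dialect: comma-separated with a header row and columns
``case_id,time_min,temperature_c[,label...]``. The delimiter and column
names are configurable on every reader/writer.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, RowParseError, ValidationError

__all__ = [
    "TemperatureTrace",
    "LabelVector",
    "FilterConfig",
    "ValidationVerdict",
    "MIN_READINGS",
    "read_traces",
    "read_labeled",
    "write_traces",
    "write_labels",
    "validate_trace",
]

#: Minimum reading count for a case to be eligible for analysis.
MIN_READINGS = 3

CASE_COL = "case_id"
TIME_COL = "time_min"
TEMP_COL = "temperature_c"


@dataclass(frozen=True)
class TemperatureTrace:
    """One case's readings, sorted by time.

    Parameters
    ----------
    case_id:
        Opaque case identifier.
    times:
        Minutes from case start, strictly increasing, non-negative.
    temperatures:
        Temperature in °C, one per time point.
    """

    case_id: str
    times: np.ndarray
    temperatures: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temperatures", temps)
        if times.ndim != 1 or temps.ndim != 1:
            raise ValidationError("times and temperatures must be 1-D")
        if times.shape != temps.shape:
            raise ValidationError(
                f"case {self.case_id!r}: {times.size} times vs {temps.size} temperatures"
            )
        if times.size and np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"case {self.case_id!r}: times must be strictly increasing"
            )
        if times.size and times[0] < 0:
            raise ValidationError(f"case {self.case_id!r}: negative time")

    def __len__(self) -> int:
        return self.times.size

    @property
    def readings(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.temperatures.tolist()))


@dataclass(frozen=True)
class LabelVector:
    """Per-reading binary adjudication aligned to a trace (1 = artifact)."""

    case_id: str
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 1:
            raise ValidationError("labels must be 1-D")
        if labels.size and not np.isin(labels, (0, 1)).all():
            raise ValidationError("labels must be binary (0 = valid, 1 = artifact)")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_artifacts(self) -> int:
        return int(self.labels.sum())


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class FilterConfig:
    """All filtering and summary thresholds, with study defaults.

    ``slope_threshold`` is in °C per minute (the same units as
    ``gap_slope_threshold``); both slope comparisons use absolute values
    and strict inequalities.
    """

    temp_min: float = 32.0
    temp_max: float = 40.0
    slope_threshold: float = 0.08
    jump_threshold: float = 0.25
    gap_threshold: float = 5.0
    min_readings_after_gap: int = 5
    gap_slope_threshold: float = 0.35
    hypothermia_threshold: float = 36.0

    def __post_init__(self):
        if not self.temp_min < self.temp_max:
            raise ValidationError(
                f"temp_min ({self.temp_min}) must be < temp_max ({self.temp_max})"
            )
        for name in (
            "slope_threshold",
            "jump_threshold",
            "gap_threshold",
            "min_readings_after_gap",
            "gap_slope_threshold",
            "hypothermia_threshold",
        ):
            _positive(name, getattr(self, name))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "FilterConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown FilterConfig fields: {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})  # type: ignore[arg-type]

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        """Load from a YAML or JSON file mirroring the field names."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ValidationVerdict:
    eligible: bool
    reason: str | None = None


def validate_trace(trace: TemperatureTrace) -> ValidationVerdict:
    """Eligibility per the study inclusion rule: at least 3 readings."""
    n = len(trace)
    if n < MIN_READINGS:
        return ValidationVerdict(
            False, f"case {trace.case_id!r} has {n} readings (< {MIN_READINGS})"
        )
    return ValidationVerdict(True)


def _to_minutes(series: pd.Series, case_id: str) -> np.ndarray:
    """Coerce a per-case time column to minutes from first reading.

    Accepts numeric minutes directly, or ISO-8601 timestamps which are
    converted to minutes relative to the earliest timestamp in the case.
    """
    numeric = pd.to_numeric(series, errors="coerce")
    if not numeric.isna().any():
        return numeric.to_numpy(dtype=float)
    stamps = pd.to_datetime(series, errors="coerce", format="ISO8601")
    if stamps.isna().any():
        mask = (stamps.isna() & numeric.isna()).to_numpy()
        pos = int(np.nonzero(mask)[0][0])
        line = int(series.index[pos]) + 2  # +1 header, +1 zero-based
        raise RowParseError(
            f"case {case_id!r}: unparseable time value {series.iloc[pos]!r} "
            f"on line {line}",
            line=line,
        )
    delta = stamps - stamps.min()
    return (delta.dt.total_seconds() / 60.0).to_numpy(dtype=float)


def _read_table(
    path: str | Path,
    delimiter: str,
    required: Sequence[str],
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _parse_numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    if values.isna().any():
        pos = int(np.nonzero(values.isna().to_numpy())[0][0])
        line = int(values.index[pos]) + 2
        raise RowParseError(
            f"non-numeric value {df[col].iloc[pos]!r} in column {col!r} "
            f"on line {line}",
            line=line,
        )
    return values.to_numpy(dtype=float)


def read_traces(
    path: str | Path,
    *,
    delimiter: str = ",",
    case_col: str = CASE_COL,
    time_col: str = TIME_COL,
    temp_col: str = TEMP_COL,
) -> list[TemperatureTrace]:
    """Read traces from a delimited file, one trace per distinct case id.

    Readings are sorted ascending by time within each case. Duplicate
    (case, time) pairs raise :class:`ValidationError` — the filtering
    algorithms assume distinct successive times.
    """
    df = _read_table(path, delimiter, (case_col, time_col, temp_col))
    traces: list[TemperatureTrace] = []
    if df.empty:
        return traces
    for case_id, group in df.groupby(case_col, sort=False):
        times = _to_minutes(group[time_col], str(case_id))
        temps = _parse_numeric(group, temp_col)
        order = np.argsort(times, kind="stable")
        times, temps = times[order], temps[order]
        if np.any(np.diff(times) == 0):
            dup = times[np.nonzero(np.diff(times) == 0)[0][0]]
            raise ValidationError(
                f"case {case_id!r}: duplicate timestamp at t={dup} min"
            )
        traces.append(TemperatureTrace(str(case_id), times, temps))
    return traces


def write_traces(
    traces: Iterable[TemperatureTrace],
    path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    frames = [
        pd.DataFrame(
            {CASE_COL: t.case_id, TIME_COL: t.times, TEMP_COL: t.temperatures}
        )
        for t in traces
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=[CASE_COL, TIME_COL, TEMP_COL])
    )
    out.to_csv(path, sep=delimiter, index=False)


def write_labels(
    traces: Sequence[TemperatureTrace],
    labels: Mapping[str, LabelVector] | Mapping[str, Mapping[str, LabelVector]],
    path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    """Write traces with aligned label columns.

    ``labels`` maps a column suffix (e.g. rater or algorithm name) to a
    per-case mapping ``{case_id: LabelVector}``; a plain
    ``{case_id: LabelVector}`` mapping is written as a single ``label``
    column. Output re-reads losslessly via :func:`read_labeled`.
    """
    flat = _normalise_label_map(labels)
    for name, by_case in flat.items():
        for trace in traces:
            vec = by_case.get(trace.case_id)
            if vec is None:
                raise ValidationError(
                    f"label set {name!r} missing case {trace.case_id!r}"
                )
            if len(vec) != len(trace):
                raise ValidationError(
                    f"label set {name!r}, case {trace.case_id!r}: "
                    f"{len(vec)} labels for {len(trace)} readings"
                )
    rows = []
    for trace in traces:
        frame = pd.DataFrame(
            {CASE_COL: trace.case_id, TIME_COL: trace.times, TEMP_COL: trace.temperatures}
        )
        for name, by_case in flat.items():
            frame[name] = by_case[trace.case_id].labels
        rows.append(frame)
    columns = [CASE_COL, TIME_COL, TEMP_COL, *flat.keys()]
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=columns)
    out.to_csv(path, sep=delimiter, index=False)


def _normalise_label_map(labels) -> dict[str, dict[str, LabelVector]]:
    if not labels:
        return {"label": {}}
    first = next(iter(labels.values()))
    if isinstance(first, LabelVector):
        return {"label": dict(labels)}
    return {str(k): dict(v) for k, v in labels.items()}


def read_labeled(
    path: str | Path,
    *,
    delimiter: str = ",",
) -> tuple[list[TemperatureTrace], dict[str, dict[str, LabelVector]]]:
    """Read a labeled file back into traces plus label sets.

    Every column named ``label`` or starting with ``label_`` becomes one
    label set keyed by its full column name.
    """
    df = _read_table(path, delimiter, (CASE_COL, TIME_COL, TEMP_COL))
    label_cols = [c for c in df.columns if c == "label" or c.startswith("label_")]
    traces = read_traces(path, delimiter=delimiter)
    label_sets: dict[str, dict[str, LabelVector]] = {c: {} for c in label_cols}
    if df.empty:
        return traces, label_sets
    for case_id, group in df.groupby(CASE_COL, sort=False):
        times = _to_minutes(group[TIME_COL], str(case_id))
        order = np.argsort(times, kind="stable")
        for col in label_cols:
            raw = _parse_numeric(group, col)[order]
            label_sets[col][str(case_id)] = LabelVector(str(case_id), raw.astype(np.int8))
    return traces, label_sets


def dump_config(config: Mapping[str, object], path: str | Path) -> None:
    """Serialize an effective run configuration as JSON for reproducibility."""
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
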