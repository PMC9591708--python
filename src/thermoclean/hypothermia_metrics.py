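"""Per-case derived measures computed after artifact removal.

The hypothermia burden is a trapezoidal area in minutes×°C over retained
readings: per reading the height is max(0, threshold − T), and each
consecutive pair contributes mean height × interval width. Segments that
cross the threshold are by default *not* split at the interpolated
crossing time (heights are clipped per observed point); pass
``split_crossings=True`` for the interpolating alternative.

Mean temperature is the unweighted arithmetic mean over retained
readings (a mean of readings, not a time-weighted average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .trace_model import FilterConfig, LabelVector, TemperatureTrace

__all__ = ["CaseSummary", "hypothermia_auc", "mean_temperature", "summarize_case"]


@dataclass(frozen=True)
class CaseSummary:
    case_id: str
    mean_temperature: float
    hypothermia_auc: float
    n_retained: int
    n_flagged: int


def _retained(trace: TemperatureTrace, labels: LabelVector) -> np.ndarray:
    if len(labels) != len(trace):
        raise ValidationError(
            f"case {trace.case_id!r}: {len(labels)} labels for {len(trace)} readings"
        )
    return labels.labels == 0


def hypothermia_auc(
    trace: TemperatureTrace,
    labels: LabelVector,
    threshold: float = 36.0,
    *,
    split_crossings: bool = False,
) -> float:
    """Time-integrated hypothermia burden below ``threshold``, minutes×°C."""
    keep = _retained(trace, labels)
    if not keep.any():
        raise UndefinedMetricError(
            f"case {trace.case_id!r}: no retained readings, burden undefined"
        )
    t = trace.times[keep]
    y = trace.temperatures[keep]
    if t.size == 1:
        return 0.0
    if not split_crossings:
        h = np.maximum(0.0, threshold - y)
        return float(np.sum((h[:-1] + h[1:]) / 2.0 * np.diff(t)))
    total = 0.0
    for (t0, y0), (t1, y1) in zip(zip(t, y), zip(t[1:], y[1:])):
        h0, h1 = threshold - y0, threshold - y1
        if h0 <= 0 and h1 <= 0:
            continue
        if h0 >= 0 and h1 >= 0:
            total += (h0 + h1) / 2.0 * (t1 - t0)
            continue
        # one side above threshold: triangle from the interpolated crossing
        tc = t0 + (t1 - t0) * h0 / (h0 - h1)
        if h0 > 0:
            total += h0 / 2.0 * (tc - t0)
        else:
            total += h1 / 2.0 * (t1 - tc)
    return float(total)


def mean_temperature(trace: TemperatureTrace, labels: LabelVector) -> float:
    keep = _retained(trace, labels)
    if not keep.any():
        raise UndefinedMetricError(
            f"case {trace.case_id!r}: no retained readings, mean undefined"
        )
    return float(trace.temperatures[keep].mean())


def summarize_case(
    trace: TemperatureTrace,
    labels: LabelVector,
    config: FilterConfig | None = None,
) -> CaseSummary:
    config = config or FilterConfig()
    n_flagged = labels.n_artifacts
    return CaseSummary(
        case_id=trace.case_id,
        mean_temperature=mean_temperature(trace, labels),
        hypothermia_auc=hypothermia_auc(trace, labels, config.hypothermia_threshold),
        n_retained=len(trace) - n_flagged,
        n_flagged=n_flagged,
    )
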