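"""Plausibility bounds and the two artifact-reduction algorithms.

Both algorithms first remove physiologically implausible readings
(outside the open interval (32, 40) °C by default; the bounds themselves
are retained). The *slope* algorithm then slides a 3-reading window over
the surviving readings: a center reading whose window has |OLS slope|
above the slope threshold is excluded when its absolute change from the
previous surviving reading also exceeds the jump threshold. Excluded
readings are removed before subsequent windows are formed, so the scan
always works on "the last valid" neighbours.

The *interval* algorithm looks at recording gaps longer than the gap
threshold: a short post-gap segment (fewer readings than the minimum) is
discarded wholesale; a long one is bridged from the last valid pre-gap
reading, discarding leading post-gap readings one at a time while the
bridge slope magnitude stays at or above the gap-slope threshold.

All threshold comparisons are strict, and slopes are compared in
absolute value (artifacts include both dips and spikes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .trace_model import FilterConfig, LabelVector, TemperatureTrace

__all__ = [
    "RULE_PLAUSIBILITY",
    "RULE_SLOPE",
    "RULE_JUMP",
    "RULE_GAP_SHORT",
    "RULE_GAP_SLOPE",
    "ALGORITHMS",
    "FilterResult",
    "ols_slope",
    "plausibility_filter",
    "slope_filter",
    "interval_filter",
    "run_algorithm",
]

logger = logging.getLogger(__name__)

RULE_PLAUSIBILITY = "plausibility"
RULE_SLOPE = "slope"
RULE_JUMP = "jump"
RULE_GAP_SHORT = "gap_short_segment"
RULE_GAP_SLOPE = "gap_slope"

ALGORITHMS = ("slope", "interval")


@dataclass(frozen=True)
class FilterResult:
    """Labels plus per-reading provenance of the rule that fired first.

    ``flags_by_rule[i]`` is ``None`` for retained readings and one of the
    ``RULE_*`` tags for flagged ones.
    """

    labels: LabelVector
    flags_by_rule: tuple[str | None, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.flags_by_rule):
            raise ValidationError("labels and provenance tags differ in length")
        for lab, tag in zip(self.labels.labels, self.flags_by_rule):
            if bool(lab) != (tag is not None):
                raise ValidationError("provenance tags inconsistent with labels")

    @property
    def n_flagged(self) -> int:
        return self.labels.n_artifacts


def ols_slope(times, temperatures) -> float:
    """Ordinary least-squares slope of temperature on time, °C per minute.

    Used for the 3-adjacent-reading linear fit; accepts any >=2 points
    with distinct times.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(temperatures, dtype=float)
    if t.size < 2:
        raise DegenerateInputError("slope needs at least 2 points")
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0:
        raise DegenerateInputError("repeated time values in slope fit")
    return float(np.dot(tc, y - y.mean()) / denom)


def plausibility_filter(
    trace: TemperatureTrace, config: FilterConfig | None = None
) -> FilterResult:
    """Flag readings strictly outside [temp_min, temp_max]."""
    config = config or FilterConfig()
    temps = trace.temperatures
    flagged = (temps < config.temp_min) | (temps > config.temp_max)
    tags = tuple(RULE_PLAUSIBILITY if f else None for f in flagged)
    return FilterResult(LabelVector(trace.case_id, flagged.astype(np.int8)), tags)


def _merge(trace: TemperatureTrace, base: FilterResult, extra: dict[int, str]) -> FilterResult:
    labels = base.labels.labels.copy()
    tags = list(base.flags_by_rule)
    for idx, rule in extra.items():
        labels[idx] = 1
        tags[idx] = rule
    return FilterResult(LabelVector(trace.case_id, labels), tuple(tags))


def slope_filter(
    trace: TemperatureTrace, config: FilterConfig | None = None
) -> FilterResult:
    """Algorithm 1: 3-point sliding-window slope with jump confirmation.

    Scans left to right over readings surviving the plausibility filter.
    The trailing (most recent) reading of each 3-reading window is an
    exclusion candidate when the window's |OLS slope| exceeds
    ``slope_threshold``; it is confirmed (and removed before later
    windows form) when its absolute difference from the previous
    surviving reading also exceeds ``jump_threshold``. The first two
    surviving readings are never candidates. Trailing attribution (rather
    than the window center) is what makes an isolated symmetric dip
    detectable: its centered window would have slope ~0.
    """
    config = config or FilterConfig()
    base = plausibility_filter(trace, config)
    surviving = [i for i in range(len(trace)) if base.flags_by_rule[i] is None]
    if len(surviving) < 3:
        logger.warning(
            "case %s: only %d surviving readings, slope rule skipped",
            trace.case_id,
            len(surviving),
        )
        return base
    t, y = trace.times, trace.temperatures
    extra: dict[int, str] = {}
    pos = 2
    while pos < len(surviving):
        window = surviving[pos - 2 : pos + 1]
        cand, prev = surviving[pos], surviving[pos - 1]
        slope = ols_slope(t[window], y[window])
        if abs(slope) > config.slope_threshold and (
            abs(y[cand] - y[prev]) > config.jump_threshold
        ):
            extra[cand] = RULE_SLOPE
            del surviving[pos]  # removed before the next window forms
        else:
            pos += 1
    return _merge(trace, base, extra)


def interval_filter(
    trace: TemperatureTrace, config: FilterConfig | None = None
) -> FilterResult:
    """Algorithm 2: recording-gap segmentation with bridge-slope checks.

    Surviving readings are split into segments at inter-reading gaps
    longer than ``gap_threshold`` minutes. A post-gap segment with fewer
    than ``min_readings_after_gap`` readings is flagged wholesale.
    Otherwise the bridge slope from the last valid (unflagged) reading to
    the segment head is computed; while its magnitude is at or above
    ``gap_slope_threshold`` the head is flagged and the bridge re-anchored
    on the next reading, until a bridge passes or the segment is
    exhausted.
    """
    config = config or FilterConfig()
    base = plausibility_filter(trace, config)
    surviving = [i for i in range(len(trace)) if base.flags_by_rule[i] is None]
    if not surviving:
        return base
    t, y = trace.times, trace.temperatures

    # split surviving readings into segments at gaps > threshold
    segments: list[list[int]] = [[surviving[0]]]
    for a, b in zip(surviving, surviving[1:]):
        if t[b] - t[a] > config.gap_threshold:
            segments.append([b])
        else:
            segments[-1].append(b)

    extra: dict[int, str] = {}
    last_valid: int | None = None
    for seg_no, segment in enumerate(segments):
        if seg_no == 0 or last_valid is None:
            # no usable pre-gap anchor: segment retained as-is
            last_valid = segment[-1]
            continue
        if len(segment) < config.min_readings_after_gap:
            for idx in segment:
                extra[idx] = RULE_GAP_SHORT
            continue
        kept_from: int | None = None
        for k, idx in enumerate(segment):
            bridge = (y[idx] - y[last_valid]) / (t[idx] - t[last_valid])
            if abs(bridge) < config.gap_slope_threshold:
                kept_from = k
                break
            extra[idx] = RULE_GAP_SLOPE
        if kept_from is not None:
            last_valid = segment[-1]
    return _merge(trace, base, extra)


def run_algorithm(
    trace: TemperatureTrace,
    config: FilterConfig | None = None,
    which: str = "slope",
) -> FilterResult:
    """Apply plausibility bounds plus the chosen algorithm."""
    if which == "slope":
        return slope_filter(trace, config)
    if which == "interval":
        return interval_filter(trace, config)
    raise ValidationError(f"unknown algorithm {which!r}; choose from {ALGORITHMS}")
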