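"""Naive, independently coded re-implementations used as test oracles.

These deliberately avoid the package's code paths: slopes come from
np.polyfit, areas from np.trapezoid, and every window/segment is
recomputed from scratch from a freshly rebuilt point list after each
removal.
"""

from __future__ import annotations

import numpy as np


def naive_plausibility(temps, lo=32.0, hi=40.0) -> set[int]:
    return {i for i, y in enumerate(temps) if y < lo or y > hi}


def naive_slope_filter(
    times,
    temps,
    lo=32.0,
    hi=40.0,
    slope_thr=0.08,
    jump_thr=0.25,
) -> set[int]:
    """Left-to-right scan; every window re-derived from a rebuilt list."""
    times = np.asarray(times, float)
    temps = np.asarray(temps, float)
    flagged = naive_plausibility(temps, lo, hi)
    pos = 2
    while True:
        alive = [i for i in range(len(times)) if i not in flagged]
        if pos >= len(alive):
            break
        trio = alive[pos - 2 : pos + 1]
        slope = np.polyfit(times[trio], temps[trio], 1)[0]
        cand, prev = alive[pos], alive[pos - 1]
        if abs(slope) > slope_thr and abs(temps[cand] - temps[prev]) > jump_thr:
            flagged.add(cand)  # list rebuilt on next loop, pos unchanged
        else:
            pos += 1
    return flagged


def naive_interval_filter(
    times,
    temps,
    lo=32.0,
    hi=40.0,
    gap_thr=5.0,
    min_after=5,
    bridge_thr=0.35,
) -> set[int]:
    """Segment-by-segment evaluation with explicit list bookkeeping."""
    times = np.asarray(times, float)
    temps = np.asarray(temps, float)
    flagged = naive_plausibility(temps, lo, hi)
    alive = [i for i in range(len(times)) if i not in flagged]
    if not alive:
        return flagged

    segments: list[list[int]] = []
    current = [alive[0]]
    for prev, nxt in zip(alive, alive[1:]):
        if times[nxt] - times[prev] > gap_thr:
            segments.append(current)
            current = [nxt]
        else:
            current.append(nxt)
    segments.append(current)

    for num, segment in enumerate(segments):
        if num == 0:
            continue
        anchors = [
            i
            for earlier in segments[:num]
            for i in earlier
            if i not in flagged
        ]
        if not anchors:
            continue  # nothing valid before the gap: segment kept
        if len(segment) < min_after:
            flagged.update(segment)
            continue
        for idx in segment:
            anchor = anchors[-1]
            rise = temps[idx] - temps[anchor]
            run = times[idx] - times[anchor]
            if abs(rise / run) < bridge_thr:
                break
            flagged.add(idx)
    return flagged


def naive_hypothermia_auc(times, temps, labels, threshold=36.0) -> float:
    """Trapezoid area of clipped heights over retained readings."""
    keep = [i for i, lab in enumerate(labels) if not lab]
    t = np.asarray(times, float)[keep]
    y = np.asarray(temps, float)[keep]
    heights = np.clip(threshold - y, 0.0, None)
    return float(np.trapezoid(heights, t)) if len(keep) > 1 else 0.0


def random_trace(rng: np.random.Generator, max_len: int = 30):
    """A small random trace exercising every filtering rule."""
    n = int(rng.integers(3, max_len + 1))
    dt = rng.uniform(0.2, 8.0, size=n - 1)  # some gaps exceed 5 min
    times = np.concatenate([[0.0], np.cumsum(dt)])
    temps = 36.0 + np.cumsum(rng.normal(0.0, 0.5, size=n))
    wild = rng.random(n) < 0.12
    temps[wild] = rng.uniform(25.0, 42.0, size=int(wild.sum()))
    return times, temps
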