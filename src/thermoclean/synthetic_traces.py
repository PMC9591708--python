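"""Seeded generator of anesthesia-typical temperature traces with
truth-labeled injected artifacts.

Clean traces follow the usual intraoperative pattern: an initial core
temperature around 36.5 °C, a linear decline of 0.01–0.03 °C/min to a
nadir, a plateau, then slow rewarming, sampled roughly once a minute
with jitter and occasional benign recording gaps. Reading counts are
log-normal, matching a median of ~103 readings per case with a wide
interquartile spread, truncated at the 3-reading eligibility minimum.

Injected artifact kinds:

``fall_out_dip``
    1–3 readings dropping toward ambient temperatures in [24, 34] °C
    (some inside the plausibility band, so the slope rule is exercised).
``warm_up_ramp``
    2–4 readings starting several degrees low and ramping steeply back
    toward core temperature, as a probe warms up after (re)insertion.
``post_gap_garbage``
    a recording gap longer than 5 minutes followed by 1–4 erratic
    readings before the trace resumes.

Placement keeps events and benign gaps apart, away from the trace ends,
and guarantees at least 5 readings after every inserted gap, so that
with the default thresholds the filtering algorithms never flag clean
readings on generated traces (benign gaps are also suppressed near the
trace end for the same reason).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .trace_model import LabelVector, TemperatureTrace, write_labels

__all__ = [
    "ARTIFACT_KINDS",
    "SimulationParams",
    "generate_trace",
    "generate_cohort",
    "simulate_raters",
    "write_cohort",
]

ARTIFACT_KINDS = ("fall_out_dip", "warm_up_ramp", "post_gap_garbage")

_PAD = 6  # minimum reading separation between injected features


@dataclass(frozen=True)
class SimulationParams:
    n_cases: int = 200
    readings_median: float = 103.0
    readings_iqr: tuple[float, float] = (51.0, 185.5)
    sampling_interval: float = 1.0
    interval_jitter: float = 0.25
    baseline_start: float = 36.5
    baseline_sd: float = 0.15
    cooling_rate: tuple[float, float] = (0.01, 0.03)
    nadir_drop: tuple[float, float] = (0.6, 1.6)
    plateau_dwell: tuple[float, float] = (20.0, 60.0)
    rewarm_rate: tuple[float, float] = (0.002, 0.008)
    measurement_noise_sd: float = 0.02
    artifact_rate: float = 0.01
    artifact_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    gap_rate: float = 0.01
    gap_length: tuple[float, float] = (6.0, 15.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("artifact_rate", "gap_rate", "interval_jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if len(self.artifact_mix) != len(ARTIFACT_KINDS):
            raise ValidationError(
                f"artifact_mix needs {len(ARTIFACT_KINDS)} proportions"
            )
        if any(p < 0 for p in self.artifact_mix) or not np.isclose(
            sum(self.artifact_mix), 1.0
        ):
            raise ValidationError("artifact_mix must be non-negative and sum to 1")
        if self.n_cases < 1:
            raise ValidationError("n_cases must be positive")
        if self.gap_length[0] <= 5.0:
            raise ValidationError("gap_length must start above the 5-minute gap rule")

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    # one master seed fans out deterministically, so any case regenerates alone
    return np.random.default_rng(np.random.SeedSequence([seed, case_index]))


def _reading_count(params: SimulationParams, rng: np.random.Generator) -> int:
    q1, q3 = params.readings_iqr
    sigma = np.log(q3 / q1) / (2.0 * stats.norm.ppf(0.75))
    n = int(round(rng.lognormal(np.log(params.readings_median), sigma)))
    return max(3, n)


def _clean_curve(
    n: int, params: SimulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Times (pre-gap) and noiseless-then-noised core temperatures."""
    jitter = params.interval_jitter
    dt = params.sampling_interval * rng.uniform(1 - jitter, 1 + jitter, size=max(n - 1, 0))
    times = np.concatenate([[0.0], np.cumsum(dt)])
    baseline = params.baseline_start + rng.normal(0.0, params.baseline_sd)
    cool = rng.uniform(*params.cooling_rate)
    nadir = baseline - rng.uniform(*params.nadir_drop)
    dwell = rng.uniform(*params.plateau_dwell)
    rewarm = rng.uniform(*params.rewarm_rate)
    t_nadir = (baseline - nadir) / cool
    temps = np.where(
        times < t_nadir,
        baseline - cool * times,
        np.where(
            times < t_nadir + dwell,
            nadir,
            np.minimum(baseline, nadir + rewarm * (times - t_nadir - dwell)),
        ),
    )
    temps = temps + rng.normal(0.0, params.measurement_noise_sd, size=n)
    return times, temps


def _place(
    taken: np.ndarray,
    rng: np.random.Generator,
    span: int,
    lo: int,
    hi: int,
    tries: int = 60,
) -> int | None:
    """Pick a start index in [lo, hi) whose padded span is free, or None."""
    if hi <= lo:
        return None
    for _ in range(tries):
        p = int(rng.integers(lo, hi))
        a, b = max(0, p - _PAD), min(taken.size, p + span + _PAD)
        if not taken[a:b].any():
            taken[p : p + span] = True
            return p
    return None


def generate_trace(
    params: SimulationParams, case_index: int
) -> tuple[TemperatureTrace, LabelVector, dict]:
    """One synthetic case: trace, truth labels, and an event inventory."""
    rng = _case_rng(params.seed, case_index)
    n = _reading_count(params, rng)
    times, temps = _clean_curve(n, params, rng)
    labels = np.zeros(n, dtype=np.int8)
    inventory = {kind: 0 for kind in ARTIFACT_KINDS}
    taken = np.zeros(n, dtype=bool)

    n_artifact = rng.binomial(n, params.artifact_rate) if params.artifact_rate else 0
    budget = int(n_artifact)
    while budget > 0:
        kind = rng.choice(len(ARTIFACT_KINDS), p=np.asarray(params.artifact_mix))
        kind = ARTIFACT_KINDS[int(kind)]
        if kind == "fall_out_dip":
            k = min(int(rng.integers(1, 4)), budget)
            p = _place(taken, rng, k, 1, n - 1 - k)
            if p is None:
                break
            temps[p : p + k] = np.sort(rng.uniform(24.0, 34.0, size=k))[::-1]
        elif kind == "warm_up_ramp":
            k = min(int(rng.integers(2, 5)), max(budget, 2))
            p = _place(taken, rng, k, 1, n - 1 - k)
            if p is None:
                break
            core = temps[p - 1]
            start = core - rng.uniform(2.0, 8.0)
            temps[p : p + k] = np.linspace(start, core - 0.5, k)
        else:  # post_gap_garbage
            k = min(int(rng.integers(1, 5)), budget)
            # gap inserted before reading p; >=5 readings must follow the gap
            p = _place(taken, rng, k, 1, n - max(k, 5) - 1)
            if p is None:
                break
            gap = rng.uniform(*params.gap_length)
            times[p:] += gap
            core = temps[p - 1]
            sign = rng.choice([-1.0, 1.0], p=[0.8, 0.2])
            offsets = rng.uniform(0.45, 0.9, size=k) * gap
            temps[p : p + k] = core + sign * offsets
        labels[p : p + k] = 1
        inventory[kind] += 1
        budget -= k

    # benign gaps, kept clear of events and of the trace end
    if params.gap_rate and n > 2 * _PAD:
        n_gaps = rng.binomial(n, params.gap_rate)
        for _ in range(n_gaps):
            p = _place(taken, rng, 1, _PAD, n - _PAD)
            if p is None:
                break
            times[p:] += rng.uniform(*params.gap_length)
            taken[p] = False  # gap occupies no reading; keep the pad only
            a, b = max(0, p - _PAD), min(n, p + 1 + _PAD)
            taken[a:b] = True

    case_id = f"case_{case_index:04d}"
    trace = TemperatureTrace(case_id, times, temps)
    truth = LabelVector(case_id, labels)
    inventory["n_artifact_readings"] = int(labels.sum())
    return trace, truth, inventory


def generate_cohort(
    params: SimulationParams,
) -> tuple[list[tuple[TemperatureTrace, LabelVector]], dict]:
    """n_cases (trace, truth) pairs plus a reproducibility manifest."""
    pairs: list[tuple[TemperatureTrace, LabelVector]] = []
    cases = []
    total = flagged = 0
    for i in range(params.n_cases):
        trace, truth, inventory = generate_trace(params, i)
        pairs.append((trace, truth))
        total += len(trace)
        flagged += truth.n_artifacts
        cases.append(
            {
                "case_id": trace.case_id,
                "case_index": i,
                "seed": [params.seed, i],
                "n_readings": len(trace),
                "events": inventory,
            }
        )
    manifest = {
        "params": params.to_dict(),
        "n_cases": params.n_cases,
        "total_readings": total,
        "total_artifact_readings": flagged,
        "empirical_artifact_rate": flagged / total if total else 0.0,
        "cases": cases,
    }
    return pairs, manifest


def simulate_raters(
    truth: LabelVector,
    miss_rates: float | Sequence[float],
    false_alarm_rates: float | Sequence[float],
    seed: int,
    n_raters: int = 3,
) -> list[LabelVector]:
    """Raters as independent miss / false-alarm perturbations of truth."""
    miss = np.broadcast_to(np.asarray(miss_rates, dtype=float), (n_raters,))
    fa = np.broadcast_to(np.asarray(false_alarm_rates, dtype=float), (n_raters,))
    if ((miss < 0) | (miss > 1) | (fa < 0) | (fa > 1)).any():
        raise ValidationError("error rates must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_919]))
    out = []
    base = truth.labels.astype(bool)
    for r in range(n_raters):
        u = rng.random(base.size)
        labels = np.where(base, u >= miss[r], u < fa[r]).astype(np.int8)
        out.append(LabelVector(truth.case_id, labels))
    return out


def write_cohort(
    pairs: Sequence[tuple[TemperatureTrace, LabelVector]],
    manifest: dict,
    outdir: str | Path,
) -> None:
    """One CSV per case, plus truth.csv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces = [t for t, _ in pairs]
    truth = {t.case_id: lv for t, lv in pairs}
    for trace, labels in pairs:
        write_labels([trace], {trace.case_id: labels}, outdir / f"{trace.case_id}.csv")
    write_labels(traces, truth, outdir / "truth.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
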