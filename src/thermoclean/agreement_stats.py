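"""Evaluation harness: consensus, classification metrics, agreement
statistics, resampling diagnostics, and agreement-study sample size.

Notable method choices
----------------------
* Binomial CIs default to the normal (Wald) approximation; Wilson is
  available via ``method="wilson"`` (delegated to statsmodels).
* Gwet's AC1 uses the multi-rater average-pairwise-agreement form with
  prevalence-based chance agreement ``2*pi*(1-pi)`` and Gwet's
  conditional variance estimator; the CI uses a t quantile on n-1 df.
* Bland-Altman limits of agreement use a fixed 1.96 multiplier on the
  sample (n-1) SD of paired differences.
* The agreement-study sample size iterates n upward under an approximate
  power formula for both limits of agreement falling inside ±delta: two
  one-sided comparisons against a central-t critical value
  (``variant="approx_t"``, the default, validated against a published
  worked instance); ``"exact_nct"`` swaps in the noncentral-t tail and
  ``"normal"`` a pure normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InfeasibleDesignError, ValidationError
from .trace_model import LabelVector

__all__ = [
    "ConfusionCounts",
    "AgreementReport",
    "SampleSizeSpec",
    "JackknifeResult",
    "majority_vote",
    "confusion",
    "classification_metrics",
    "artifact_rate",
    "gwet_ac1",
    "bland_altman",
    "find_clusters",
    "jackknife_summaries",
    "loa_agreement_power",
    "agreement_sample_size",
]


# ---------------------------------------------------------------------------
# consensus and confusion


def _aligned(vectors: Sequence[LabelVector]) -> np.ndarray:
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValidationError(f"label vectors differ in length: {sorted(lengths)}")
    return np.vstack([v.labels for v in vectors])


def majority_vote(rater_labels: Sequence[LabelVector]) -> LabelVector:
    """Consensus label: artifact iff a strict majority of raters says so.

    With the study's three raters this is agreement among at least 2 of 3.
    """
    if len(rater_labels) < 2:
        raise ValidationError("majority vote needs at least 2 raters")
    votes = _aligned(rater_labels)
    consensus = (votes.sum(axis=0) * 2 > votes.shape[0]).astype(np.int8)
    return LabelVector(rater_labels[0].case_id, consensus)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def confusion(predicted: LabelVector, reference: LabelVector) -> ConfusionCounts:
    """Tally predicted vs reference artifact labels (artifact = positive)."""
    p, r = _aligned([predicted, reference])
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (r == 1))),
        fp=int(np.sum((p == 1) & (r == 0))),
        fn=int(np.sum((p == 0) & (r == 1))),
        tn=int(np.sum((p == 0) & (r == 0))),
    )


def classification_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, precision and F1 for the artifact class.

    A metric whose denominator vanishes is reported as ``None`` and the
    vanished denominator is named under the ``"undefined"`` key.
    """
    undefined: dict[str, str] = {}

    def ratio(num: int, den: int, name: str, den_desc: str) -> float | None:
        if den == 0:
            undefined[name] = f"denominator {den_desc} is zero"
            return None
        return num / den

    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity", "tp+fn")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity", "tn+fp")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision", "tp+fp")
    if prec is None or sens is None:
        undefined.setdefault("f_score", "precision or sensitivity undefined")
        f1 = None
    elif prec + sens == 0:
        undefined["f_score"] = "denominator precision+sensitivity is zero"
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f_score": f1,
        "undefined": undefined,
    }


def artifact_rate(
    n_artifacts: int,
    n_total: int,
    confidence: float = 0.95,
    method: str = "normal",
) -> dict[str, float]:
    """Proportion of artifact readings with a binomial CI.

    ``method`` is "normal" (Wald, default) or "wilson".
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_artifacts <= n_total:
        raise ValidationError("n_artifacts must be in [0, n_total]")
    lo, hi = proportion_confint(n_artifacts, n_total, alpha=1 - confidence, method=method)
    return {"estimate": n_artifacts / n_total, "ci_low": float(lo), "ci_high": float(hi)}


# ---------------------------------------------------------------------------
# chance-corrected agreement


def gwet_ac1(
    rater_labels: Sequence[LabelVector], confidence: float = 0.95
) -> dict[str, float]:
    """Gwet's AC1 agreement coefficient for >=2 raters on binary labels.

    AC1 = (Pa − Pe)/(1 − Pe) with Pa the per-item average pairwise
    observed agreement and Pe = 2·π̂·(1−π̂) where π̂ is the mean artifact
    prevalence across raters. The standard error follows Gwet's
    conditional (multi-rater) variance estimator and the CI uses a
    t quantile on n−1 df, truncated to [−1, 1].
    """
    if len(rater_labels) < 2:
        raise ValidationError("AC1 needs at least 2 raters")
    votes = _aligned(rater_labels).astype(float)  # raters x items
    r, n = votes.shape
    if n < 2:
        raise ValidationError("AC1 needs at least 2 items")

    r1 = votes.sum(axis=0)  # artifact votes per item
    r0 = r - r1
    # per-item pairwise agreement among r raters
    pa_i = (r1 * (r1 - 1) + r0 * (r0 - 1)) / (r * (r - 1))
    pa = float(pa_i.mean())
    pi_hat = float(votes.mean(axis=1).mean())  # mean prevalence across raters
    pe = 2.0 * pi_hat * (1.0 - pi_hat)
    if pe == 1.0:
        raise ValidationError("chance agreement is 1; AC1 undefined")
    ac1 = (pa - pe) / (1.0 - pe)

    # Gwet conditional variance: per-item coefficients with a correction
    # for the chance-agreement component.
    # per-item chance term: mean over categories of (r_iq/r)*(1 - pi_q)
    # for binary categories with pi_1 = pi_hat, pi_0 = 1 - pi_hat.
    pe_i = (r1 / r) * (1.0 - pi_hat) + (r0 / r) * pi_hat
    ac1_i = (pa_i - pe) / (1.0 - pe)
    ac1_star = ac1_i - 2.0 * (1.0 - ac1) * (pe_i - pe) / (1.0 - pe)
    var = float(np.sum((ac1_star - ac1) ** 2)) / (n * (n - 1))
    se = math.sqrt(var)
    tq = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    return {
        "ac1": ac1,
        "se": se,
        "ci_low": max(-1.0, ac1 - tq * se),
        "ci_high": min(1.0, ac1 + tq * se),
    }


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class AgreementReport:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self):
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValidationError("limits of agreement must bracket the bias")


LOA_Z = 1.96  # 95% limits of agreement


def bland_altman(paired_measures: Sequence[tuple[float, float]]) -> AgreementReport:
    """Bias and 95% limits of agreement of paired differences a − b."""
    pairs = np.asarray(paired_measures, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValidationError("paired_measures must be a sequence of (a, b) pairs")
    if pairs.shape[0] < 2:
        raise ValidationError("Bland-Altman needs at least 2 pairs")
    d = pairs[:, 0] - pairs[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_Z * sd,
        loa_high=bias + LOA_Z * sd,
        n=int(d.size),
    )


# ---------------------------------------------------------------------------
# clusters


def find_clusters(labels: LabelVector, min_size: int = 3) -> list[tuple[int, int]]:
    """Maximal runs of consecutive artifact labels of length >= min_size.

    Returns (start index, run length) pairs in order of appearance.
    """
    arr = labels.labels
    clusters: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(arr):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_size:
                clusters.append((start, i - start))
            start = None
    if start is not None and len(arr) - start >= min_size:
        clusters.append((start, len(arr) - start))
    return clusters


# ---------------------------------------------------------------------------
# jackknife


@dataclass(frozen=True)
class JackknifeResult:
    statistic: str
    full_estimate: float
    loo_estimates: np.ndarray
    se: float
    influential: np.ndarray  # bool per case, against the influence threshold


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "bias": lambda d: float(d.mean()),
    "loa_low": lambda d: float(d.mean() - LOA_Z * d.std(ddof=1)),
    "loa_high": lambda d: float(d.mean() + LOA_Z * d.std(ddof=1)),
}


def jackknife_summaries(
    per_case_values: Sequence[float],
    statistic: str | Callable[[np.ndarray], float] = "bias",
    influence_threshold: float | None = None,
) -> JackknifeResult | dict[str, JackknifeResult]:
    """Leave-one-case-out re-estimates of a summary statistic.

    ``statistic`` is "bias", "loa_low", "loa_high", "loa" (returns a dict
    with both limits), or a callable. The jackknife SE uses the standard
    (n−1)/n scaling; ``influential`` marks leave-one-out estimates
    deviating from the full estimate by more than ``influence_threshold``
    (defaults to one full-sample jackknife SE).
    """
    values = np.asarray(per_case_values, dtype=float)
    if values.size < 2:
        raise ValidationError("jackknife needs at least 2 cases")
    if statistic == "loa":
        return {
            side: jackknife_summaries(values, side, influence_threshold)
            for side in ("loa_low", "loa_high")
        }
    if callable(statistic):
        func, name = statistic, getattr(statistic, "__name__", "custom")
    else:
        try:
            func, name = _STATISTICS[statistic], statistic
        except KeyError:
            raise ValidationError(
                f"unknown statistic {statistic!r}; choose from "
                f"{sorted(_STATISTICS)} or 'loa'"
            ) from None
    n = values.size
    full = func(values)
    loo = np.array([func(np.delete(values, i)) for i in range(n)])
    se = math.sqrt((n - 1) / n * float(np.sum((loo - loo.mean()) ** 2)))
    threshold = influence_threshold if influence_threshold is not None else se
    influential = np.abs(loo - full) > threshold
    return JackknifeResult(name, full, loo, se, influential)


# ---------------------------------------------------------------------------
# agreement-study sample size


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design inputs for a Bland-Altman agreement study.

    ``delta`` is the maximum allowable difference within which both
    limits of agreement must fall (same units as the differences).
    """

    mu_diff: float
    sd_diff: float
    delta: float
    confidence: float = 0.95
    ci_confidence: float = 0.95
    power: float = 0.80

    def __post_init__(self):
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")
        if not (0 < self.confidence < 1 and 0 < self.ci_confidence < 1):
            raise ValidationError("confidence levels must be in (0, 1)")
        if self.sd_diff <= 0:
            raise ValidationError("sd_diff must be positive")
        if self.delta <= abs(self.mu_diff):
            raise InfeasibleDesignError(
                f"delta ({self.delta}) must exceed |mu_diff| ({abs(self.mu_diff)})"
            )


def loa_agreement_power(n: int, spec: SampleSizeSpec, variant: str = "approx_t") -> float:
    """Power that both estimated limits of agreement fall inside ±delta.

    Agreement is concluded when the one-sided confidence bound (at
    ``ci_confidence``) of each limit of agreement lies inside ±delta; the
    two one-sided non-coverage probabilities are combined by the usual
    union bound.
    """
    if n < 2:
        return 0.0
    z_loa = stats.norm.ppf(0.5 + spec.confidence / 2.0)
    se = spec.sd_diff * math.sqrt(1.0 / n + z_loa**2 / (2.0 * (n - 1)))
    tau1 = (spec.delta - spec.mu_diff - z_loa * spec.sd_diff) / se
    tau2 = (spec.delta + spec.mu_diff - z_loa * spec.sd_diff) / se
    if variant == "approx_t":
        crit = stats.t.ppf(spec.ci_confidence, n - 1)
        power = stats.norm.cdf(tau1 - crit) + stats.norm.cdf(tau2 - crit) - 1.0
    elif variant == "exact_nct":
        crit = stats.t.ppf(spec.ci_confidence, n - 1)
        power = stats.nct.sf(crit, n - 1, tau1) + stats.nct.sf(crit, n - 1, tau2) - 1.0
    elif variant == "normal":
        crit = stats.norm.ppf(spec.ci_confidence)
        power = stats.norm.cdf(tau1 - crit) + stats.norm.cdf(tau2 - crit) - 1.0
    else:
        raise ValidationError(f"unknown power variant {variant!r}")
    return float(max(0.0, power))


def agreement_sample_size(
    spec: SampleSizeSpec, variant: str = "approx_t", n_max: int = 1_000_000
) -> int:
    """Smallest n whose limits-of-agreement power reaches the target."""
    z_loa = stats.norm.ppf(0.5 + spec.confidence / 2.0)
    if spec.delta - abs(spec.mu_diff) <= z_loa * spec.sd_diff:
        raise InfeasibleDesignError(
            "delta - |mu_diff| must exceed the half-width of the limits of "
            f"agreement ({z_loa * spec.sd_diff:.4g}); no sample size suffices"
        )
    n = 2
    while n <= n_max:
        if loa_agreement_power(n, spec, variant) >= spec.power:
            return n
        n += 1
    raise InfeasibleDesignError(f"target power not reached by n = {n_max}")
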