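import math

import numpy as np
import pytest

from thermoclean import LabelVector
from thermoclean.agreement_stats import (
    ConfusionCounts,
    SampleSizeSpec,
    agreement_sample_size,
    artifact_rate,
    bland_altman,
    classification_metrics,
    confusion,
    find_clusters,
    gwet_ac1,
    jackknife_summaries,
    loa_agreement_power,
    majority_vote,
)
from thermoclean.errors import InfeasibleDesignError, ValidationError


def lv(labels, case_id="c"):
    return LabelVector(case_id, labels)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes,expected",
        [((1, 1, 1), 1), ((1, 1, 0), 1), ((1, 0, 0), 0), ((0, 0, 0), 0)],
    )
    def test_single_reading(self, votes, expected):
        raters = [lv([v]) for v in votes]
        assert majority_vote(raters).labels[0] == expected

    def test_vectorized(self):
        raters = [lv([1, 1, 0, 0]), lv([1, 0, 1, 0]), lv([1, 1, 0, 0])]
        np.testing.assert_array_equal(majority_vote(raters).labels, [1, 1, 0, 0])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            majority_vote([lv([1]), lv([1, 0]), lv([0])])


class TestConfusion:
    def test_perfect_prediction(self):
        ref = lv([1] * 5 + [0] * 15)
        c = confusion(ref, ref)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 15, 0, 0)

    def test_all_negative_prediction(self):
        c = confusion(lv([0] * 10), lv([1, 1, 1] + [0] * 7))
        assert (c.fn, c.tn, c.tp, c.fp) == (3, 7, 0, 0)

    def test_exhaustive_combinations(self):
        c = confusion(lv([1, 1, 0, 0]), lv([1, 0, 1, 0]))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_total_partition(self):
        c = confusion(lv([1, 0, 1]), lv([0, 0, 1]))
        assert c.total == 3

    def test_addition(self):
        a = ConfusionCounts(1, 2, 3, 4)
        b = ConfusionCounts(4, 3, 2, 1)
        assert (a + b) == ConfusionCounts(5, 5, 5, 5)


class TestClassificationMetrics:
    def test_hand_derived(self):
        m = classification_metrics(ConfusionCounts(tp=1, fn=1, fp=0, tn=8))
        assert m["sensitivity"] == pytest.approx(0.5, abs=1e-12)
        assert m["specificity"] == pytest.approx(1.0, abs=1e-12)
        assert m["precision"] == pytest.approx(1.0, abs=1e-12)
        assert m["f_score"] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_perfect(self):
        m = classification_metrics(ConfusionCounts(tp=4, fn=0, fp=0, tn=6))
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "precision", "f_score"))

    def test_undefined_sensitivity_reported(self):
        m = classification_metrics(ConfusionCounts(tp=0, fn=0, fp=2, tn=8))
        assert m["sensitivity"] is None
        assert "tp+fn" in m["undefined"]["sensitivity"]
        assert m["f_score"] is None

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score, precision_score, recall_score

        for _ in range(50):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 30, size=4))
            y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            m = classification_metrics(ConfusionCounts(tp, fp, fn, tn))
            assert m["sensitivity"] == pytest.approx(recall_score(y_true, y_pred))
            assert m["precision"] == pytest.approx(precision_score(y_true, y_pred))
            assert m["f_score"] == pytest.approx(f1_score(y_true, y_pred))


class TestArtifactRate:
    def test_paper_scale_counts_round_to_point_estimate(self):
        out = artifact_rate(289, 27683)
        assert round(out["estimate"], 2) == 0.01

    def test_zero_artifacts(self):
        assert artifact_rate(0, 100)["estimate"] == 0.0

    def test_hand_wald_interval(self):
        out = artifact_rate(50, 100)
        z = 1.959963984540054  # 97.5% normal quantile
        assert out["estimate"] == pytest.approx(0.5, abs=1e-12)
        assert out["ci_low"] == pytest.approx(0.5 - z * 0.05, abs=1e-9)
        assert out["ci_high"] == pytest.approx(0.5 + z * 0.05, abs=1e-9)

    def test_wilson_option_differs(self):
        wald = artifact_rate(5, 10)
        wilson = artifact_rate(5, 10, method="wilson")
        assert wald["ci_low"] != wilson["ci_low"]

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            artifact_rate(1, 0)
        with pytest.raises(ValidationError):
            artifact_rate(5, 3)


class TestGwetAc1:
    def test_perfect_agreement_is_one(self):
        raters = [lv([1, 0, 1, 0, 0])] * 3
        assert gwet_ac1(raters)["ac1"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_three_raters(self):
        # 10 items, unanimous "valid" on 9, split on the last (one artifact
        # vote). Pa = (9 + 1/3)/10 = 14/15; prevalence per rater (0.1, 0, 0)
        # so pi = 1/30 and Pe = 2*(1/30)*(29/30) = 29/450;
        # AC1 = (14/15 - 29/450)/(1 - 29/450) = 391/421.
        r1 = lv([0] * 9 + [1])
        r2 = lv([0] * 10)
        r3 = lv([0] * 10)
        out = gwet_ac1([r1, r2, r3])
        assert out["ac1"] == pytest.approx(391.0 / 421.0, abs=1e-10)

    def test_systematic_disagreement_negative(self):
        out = gwet_ac1([lv([1, 0]), lv([0, 1])])
        # Pa = 0, pi = 0.5, Pe = 0.5 -> AC1 = -1
        assert out["ac1"] == pytest.approx(-1.0, abs=1e-12)
        assert out["ac1"] < 0

    def test_ci_brackets_estimate(self):
        raters = [lv([0, 0, 1, 0, 1, 0, 0, 0]), lv([0, 0, 1, 0, 0, 0, 0, 0])]
        out = gwet_ac1(raters)
        assert out["ci_low"] <= out["ac1"] <= out["ci_high"]
        assert out["se"] > 0

    def test_relabeling_invariance(self, rng):
        for _ in range(20):
            votes = rng.integers(0, 2, size=(3, 15))
            raters = [lv(v) for v in votes]
            flipped = [lv(1 - v) for v in votes]
            assert gwet_ac1(raters)["ac1"] == pytest.approx(
                gwet_ac1(flipped)["ac1"], abs=1e-12
            )

    def test_too_few_raters_or_items(self):
        with pytest.raises(ValidationError):
            gwet_ac1([lv([0, 1])])
        with pytest.raises(ValidationError):
            gwet_ac1([lv([0]), lv([0])])


class TestBlandAltman:
    def test_identical_pairs(self):
        rep = bland_altman([(1.0, 1.0), (2.5, 2.5), (7.0, 7.0)])
        assert rep.bias == 0.0
        assert rep.loa_low == rep.loa_high == 0.0

    def test_constant_offset(self):
        rep = bland_altman([(a, a + 3.0) for a in (1.0, 2.0, 5.0)])
        assert rep.bias == pytest.approx(-3.0, abs=1e-12)
        assert rep.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_loa(self):
        rep = bland_altman([(1.0, 2.0), (2.0, 1.0)])  # differences -1, +1
        assert rep.bias == pytest.approx(0.0, abs=1e-12)
        assert rep.sd_diff == pytest.approx(math.sqrt(2.0), abs=1e-10)
        assert rep.loa_high == pytest.approx(1.96 * math.sqrt(2.0), abs=1e-10)
        assert rep.loa_low == pytest.approx(-1.96 * math.sqrt(2.0), abs=1e-10)

    def test_shift_equivariance(self, rng):
        pairs = [(float(a), float(b)) for a, b in rng.normal(0, 1, size=(12, 2))]
        shifted = [(a + 5.0, b) for a, b in pairs]
        base, moved = bland_altman(pairs), bland_altman(shifted)
        assert moved.bias == pytest.approx(base.bias + 5.0, abs=1e-9)
        assert moved.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)

    def test_needs_two_pairs(self):
        with pytest.raises(ValidationError):
            bland_altman([(1.0, 2.0)])


class TestFindClusters:
    def test_minimal_cluster(self):
        assert find_clusters(lv([1, 1, 1])) == [(0, 3)]

    def test_short_runs_ignored(self):
        assert find_clusters(lv([1, 1, 0, 1, 1, 1, 1])) == [(3, 4)]

    def test_no_artifacts(self):
        assert find_clusters(lv([0, 0, 0, 0])) == []

    def test_multiple_clusters_in_order(self):
        labels = lv([1, 1, 1, 0, 1, 0, 1, 1, 1, 1])
        assert find_clusters(labels) == [(0, 3), (6, 4)]

    def test_min_size_configurable(self):
        assert find_clusters(lv([1, 1, 0]), min_size=2) == [(0, 2)]

    def test_runs_cover_qualifying_readings(self, rng):
        for _ in range(50):
            labels = rng.integers(0, 2, size=30)
            clusters = find_clusters(lv(labels))
            covered = set()
            for start, length in clusters:
                assert length >= 3
                assert labels[start : start + length].all()
                # maximal: neighbours are 0 or out of range
                assert start == 0 or labels[start - 1] == 0
                end = start + length
                assert end == 30 or labels[end] == 0
                assert not (covered & set(range(start, end)))
                covered |= set(range(start, end))


class TestJackknife:
    def test_constant_values(self):
        out = jackknife_summaries([3.0, 3.0, 3.0, 3.0], "bias")
        np.testing.assert_allclose(out.loo_estimates, 3.0)
        assert out.se == 0.0
        assert not out.influential.any()

    def test_hand_computed_two_values(self):
        out = jackknife_summaries([0.0, 2.0], "bias")
        np.testing.assert_allclose(out.loo_estimates, [2.0, 0.0])
        assert out.se == pytest.approx(1.0, abs=1e-12)

    def test_cardinality(self, rng):
        values = rng.normal(size=9)
        out = jackknife_summaries(values, "bias")
        assert out.loo_estimates.size == 9

    def test_loa_returns_both_limits(self):
        out = jackknife_summaries([0.0, 1.0, 2.0, 4.0], "loa")
        assert set(out) == {"loa_low", "loa_high"}
        assert out["loa_low"].loo_estimates.size == 4

    def test_se_zero_iff_constant(self, rng):
        varied = jackknife_summaries([0.0, 1.0, 2.0], "bias")
        assert varied.se > 0

    def test_influence_flag(self):
        out = jackknife_summaries([0.0, 0.0, 0.0, 100.0], "bias", influence_threshold=10.0)
        assert out.influential.sum() == 1

    def test_needs_two_cases(self):
        with pytest.raises(ValidationError):
            jackknife_summaries([1.0], "bias")

    def test_unknown_statistic(self):
        with pytest.raises(ValidationError):
            jackknife_summaries([1.0, 2.0], "median-ish")


class TestSampleSize:
    SPEC = SampleSizeSpec(mu_diff=0.2, sd_diff=1.02, delta=2.56)

    def test_published_worked_instance(self):
        assert agreement_sample_size(self.SPEC) == 147

    def test_noncentral_variant_agrees_here(self):
        assert agreement_sample_size(self.SPEC, variant="exact_nct") == 147

    def test_monotone_in_delta(self):
        wider = SampleSizeSpec(mu_diff=0.2, sd_diff=1.02, delta=5.12)
        assert agreement_sample_size(wider) < 147

    def test_monotone_in_power(self):
        harder = SampleSizeSpec(mu_diff=0.2, sd_diff=1.02, delta=2.56, power=0.9)
        assert agreement_sample_size(harder) >= 147

    def test_monotone_in_sd(self):
        noisier = SampleSizeSpec(mu_diff=0.2, sd_diff=1.1, delta=2.56)
        assert agreement_sample_size(noisier) > 147

    def test_power_at_answer_brackets_target(self):
        assert loa_agreement_power(147, self.SPEC) >= 0.8
        assert loa_agreement_power(146, self.SPEC) < 0.8

    def test_infeasible_delta(self):
        with pytest.raises(InfeasibleDesignError):
            SampleSizeSpec(mu_diff=0.5, sd_diff=1.0, delta=0.4)

    def test_infeasible_loa_width(self):
        spec = SampleSizeSpec(mu_diff=0.0, sd_diff=1.0, delta=1.5)  # 1.96 > 1.5
        with pytest.raises(InfeasibleDesignError):
            agreement_sample_size(spec)

    def test_bad_power(self):
        with pytest.raises(ValidationError):
            SampleSizeSpec(mu_diff=0.0, sd_diff=1.0, delta=3.0, power=1.5)
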