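import numpy as np
import pandas as pd
import pytest

from deltarad.delta import (
    Enhancement,
    ResponseObservation,
    VolumeChange,
    aggregate_rvisu,
    cohort_delta,
    correlate_with_response,
    delta_percent,
    paired_change_tests,
    score_response,
)

import oracle
from conftest import cohort_from_feature_arrays, minimal_clinical


class TestDeltaPercent:
    @pytest.mark.parametrize("p1,p2,want", [
        (10.0, 15.0, 50.0),
        (7.3, 7.3, 0.0),
        (-20.0, -30.0, 50.0),       # signed: further from zero on a negative base
        (30.342, -60.893, -300.69), # density mean crossing zero after ablation
    ])
    def test_values(self, p1, p2, want):
        assert delta_percent(p1, p2) == pytest.approx(want, abs=0.01)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        # cohort aggregation is per-patient-then-average: the ratio of the
        # cohort means (-300.7% here) need not equal the mean of the
        # per-patient ratios
        p1 = np.array([10.0, 50.0])
        p2 = np.array([-20.0, -50.0])
        per_patient = [delta_percent(a, b) for a, b in zip(p1, p2)]
        assert np.mean(per_patient) == pytest.approx((-300 - 200) / 2)
        ratio_of_means = delta_percent(p1.mean(), p2.mean())
        assert ratio_of_means != pytest.approx(np.mean(per_patient))

    def test_near_zero_baseline_is_undefined(self):
        assert np.isnan(delta_percent(0.0, 5.0))
        assert np.isnan(delta_percent(1e-9, 5.0, p1_floor=1e-6))

    def test_nan_propagates(self):
        assert np.isnan(delta_percent(np.nan, 5.0))
        assert np.isnan(delta_percent(5.0, np.nan))

    def test_sign_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p1 = rng.uniform(0.1, 100)
            p2 = rng.uniform(-100, 100)
            assert delta_percent(p1, p2) == pytest.approx(
                -delta_percent(p1, 2 * p1 - p2), abs=1e-9)


class TestCohortDelta:
    def test_mean_and_sd_of_ratios(self):
        clin = minimal_clinical(2)
        cohort = cohort_from_feature_arrays(
            {"contrast": ([10.0, 10.0], [11.0, 13.0])}, clin)
        delta, summary = cohort_delta(cohort, features=["contrast"])
        assert summary.loc["contrast", "mean"] == pytest.approx(20.0)
        assert summary.loc["contrast", "sd"] == pytest.approx(14.1421, rel=1e-4)

    def test_identical_pre_post_gives_zero_means(self):
        clin = minimal_clinical(5)
        vals = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        cohort = cohort_from_feature_arrays({"mean": (vals, vals.copy())}, clin)
        delta, summary = cohort_delta(cohort, features=["mean"])
        assert summary.loc["mean", "mean"] == 0.0
        assert (delta["mean"] == 0).all()

    def test_undefined_baselines_excluded_and_counted(self):
        clin = minimal_clinical(4)
        pre = [10.0, 0.0, 10.0, 10.0]
        post = [20.0, 5.0, 15.0, 5.0]
        cohort = cohort_from_feature_arrays({"f": (pre, post)}, clin)
        delta, summary = cohort_delta(cohort, features=["f"])
        assert summary.loc["f", "n"] == 3
        assert summary.loc["f", "n_undefined"] == 1


class TestScoreResponse:
    @pytest.mark.parametrize("enh,vol,want", [
        (Enhancement.NONE, VolumeChange.SHRUNK, 5),
        (Enhancement.NONE, VolumeChange.UNCHANGED_OR_SLIGHTLY_ENLARGED, 4),
        (Enhancement.RESIDUAL_LT50, VolumeChange.SHRUNK, 3),
        (Enhancement.RESIDUAL_LT50, VolumeChange.ENLARGED, 3),
        (Enhancement.RESIDUAL_GE50, VolumeChange.UNCHANGED_OR_SLIGHTLY_ENLARGED, 2),
        (Enhancement.NEW_ZONE, VolumeChange.SHRUNK, 2),
    ])
    def test_rubric(self, enh, vol, want):
        assert score_response(ResponseObservation(enh, vol)) == want

    def test_rubric_total_over_defined_combinations(self):
        defined = 0
        for enh in Enhancement:
            for vol in VolumeChange:
                if enh is Enhancement.NONE and vol is VolumeChange.ENLARGED:
                    continue
                s = score_response(ResponseObservation(enh, vol))
                assert s in (2, 3, 4, 5)
                defined += 1
        assert defined == len(Enhancement) * len(VolumeChange) - 1

    def test_undefined_combination_is_an_error(self):
        with pytest.raises(ValueError):
            score_response(ResponseObservation(Enhancement.NONE, VolumeChange.ENLARGED))


class TestAggregateRvisu:
    @pytest.mark.parametrize("scores,mean,complete", [
        ((5, 5, 5), 5.0, True),
        ((5, 4, 4), 4.3333, True),
        ((4, 3, 3), 3.3333, False),
    ])
    def test_mean_and_threshold(self, scores, mean, complete):
        r = aggregate_rvisu(scores)
        assert r.score == pytest.approx(mean, abs=1e-3)
        assert r.complete_ablation is complete

    def test_missing_observer_errors(self):
        with pytest.raises(ValueError):
            aggregate_rvisu((5, 4))


class TestPairedTests:
    def _cohort(self, diffs, base=100.0):
        n = len(diffs)
        clin = minimal_clinical(n)
        pre = np.full(n, base)
        return cohort_from_feature_arrays({"f": (pre, pre + np.asarray(diffs))}, clin)

    def test_normal_shift_detected_by_paired_t_with_high_power(self):
        hits = used_t = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            res = paired_change_tests(self._cohort(rng.normal(0.5, 1.0, 50)),
                                      features=["f"])[0]
            used_t += res.test_used == "paired_t"
            hits += res.p_value < 0.05
        assert hits / reps >= 0.90          # Monte-Carlo power
        assert used_t / reps > 0.9          # Shapiro gate keeps the t-test

    def test_heavy_tails_route_to_wilcoxon(self):
        wil = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            res = paired_change_tests(self._cohort(rng.standard_cauchy(50)),
                                      features=["f"])[0]
            wil += res.test_used == "wilcoxon_signed_rank"
        assert wil / reps >= 0.95

    def test_identical_pre_post_skipped(self):
        res = paired_change_tests(self._cohort(np.zeros(20)), features=["f"])[0]
        assert res.test_used == "skipped"

    def test_too_few_pairs_skipped(self):
        res = paired_change_tests(self._cohort([1.0, 2.0, 3.0]), features=["f"])[0]
        assert res.test_used == "skipped"


class TestSpearman:
    def test_monotone_is_plus_minus_one(self):
        up = correlate_with_response([1, 2, 3], [2, 3, 5], min_patients=3)
        down = correlate_with_response([1, 2, 3], [5, 3, 2], min_patients=3)
        assert up.spearman_r == pytest.approx(1.0)
        assert down.spearman_r == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        res = correlate_with_response([1, 2, 3, 4], [2, 2, 3, 5], min_patients=4)
        assert res.spearman_r == pytest.approx(0.9487, abs=1e-4)
        assert res.spearman_r == pytest.approx(
            oracle.brute_spearman([1, 2, 3, 4], [2, 2, 3, 5]), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0 = correlate_with_response(x, y).spearman_r
        r1 = correlate_with_response(np.exp(x), y).spearman_r
        r2 = correlate_with_response(x, 3 * y + 7).spearman_r
        assert r1 == pytest.approx(r0)
        assert r2 == pytest.approx(r0)

    def test_constant_input_flagged(self):
        res = correlate_with_response([1, 1, 1, 1, 1], [2, 3, 4, 5, 2])
        assert np.isnan(res.spearman_r) and "constant" in res.note
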