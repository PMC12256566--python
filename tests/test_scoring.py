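import numpy as np
import pytest

from sbrtaudit.scoring import (
    AuditResult,
    ScoringThresholds,
    aggregate_cohort,
    classify_failure_mode,
    classify_outcome,
    compare_series,
    percentages_from_counts,
    round_half_up,
)


def _metrics(case_id="soft_tissue", gamma=98.0, point=1.0, **extra):
    base = {"gamma_pass_rate_pct": gamma, "point_diff_local_pct": point}
    if case_id == "soft_tissue":
        base.update(dta_mean_lr_mm=0.1, dta_mean_ap_mm=-0.1)
    elif case_id == "spine":
        base.update(dta_max_interface_ap_mm=0.2, dta_mean_interface_lr_mm=0.1)
    else:
        base.update(dta_mean_ap_mm=0.1)
    base.update(extra)
    return base


class TestOutcomeClassification:
    @pytest.mark.parametrize(
        "gamma, expected",
        [
            (96.0, "optimal"),
            (95.0, "optimal"),  # >= 95 is optimal
            (94.99, "action"),
            (90.0, "action"),  # band is < 95 and >= 90
            (89.99, "out_of_tolerance"),
        ],
    )
    def test_gamma_band_boundaries(self, gamma, expected):
        result = classify_outcome(_metrics(gamma=gamma), "soft_tissue")
        assert result.outcome == expected

    def test_point_upper_limit_overrides_gamma(self):
        result = classify_outcome(_metrics(gamma=92.0, point=9.0), "soft_tissue")
        assert result.outcome == "out_of_tolerance"
        assert result.triggers == ["point_diff_local_pct"]

    def test_point_boundary_8pct_passes(self):
        assert classify_outcome(_metrics(point=8.0), "soft_tissue").outcome == "optimal"
        assert (
            classify_outcome(_metrics(point=8.01), "soft_tissue").outcome
            == "out_of_tolerance"
        )
        # the limit applies to the magnitude
        assert (
            classify_outcome(_metrics(point=-8.01), "soft_tissue").outcome
            == "out_of_tolerance"
        )

    def test_dta_boundaries_per_case(self):
        r = classify_outcome(_metrics(dta_mean_lr_mm=3.0), "soft_tissue")
        assert r.outcome == "optimal"
        r = classify_outcome(_metrics(dta_mean_lr_mm=3.01), "soft_tissue")
        assert r.outcome == "out_of_tolerance" and r.triggers == ["dta_mean_lr_mm"]
        # spine interface limit is 2.0 mm
        r = classify_outcome(_metrics("spine", dta_max_interface_ap_mm=2.0), "spine")
        assert r.outcome == "optimal"
        r = classify_outcome(_metrics("spine", dta_max_interface_ap_mm=-2.01), "spine")
        assert r.outcome == "out_of_tolerance"
        # lung uses the 3.0 mm limit on the AP mean
        r = classify_outcome(_metrics("lung", dta_mean_ap_mm=3.01), "lung")
        assert r.outcome == "out_of_tolerance"

    def test_missing_metric_is_error(self):
        m = _metrics()
        del m["dta_mean_ap_mm"]
        with pytest.raises(KeyError, match="missing"):
            classify_outcome(m, "soft_tissue")

    def test_outcome_partition_is_exhaustive(self):
        for gamma in (99.0, 93.0, 85.0):
            r = classify_outcome(_metrics(gamma=gamma), "soft_tissue")
            assert r.outcome in ("optimal", "action", "out_of_tolerance")


class TestFailureModes:
    def _oot(self, case_id="soft_tissue", **extra):
        m = _metrics(case_id, gamma=70.0, **extra)
        return classify_outcome(m, case_id)

    def test_uniform_shift_is_igrt_mismatch(self):
        r = self._oot(edge_displacements={"LR": (-3.0, -3.0), "AP": (-0.1, 0.1)})
        mode, agrees = classify_failure_mode(r, injected="IGRT mismatch")
        assert mode == "IGRT mismatch" and agrees

    def test_cold_delivery_is_in_volume_low(self):
        r = self._oot(
            edge_displacements={"LR": (0.1, -0.1)}, ptv_global_diff_pct=11.0
        )
        mode, _ = classify_failure_mode(r)
        assert mode == "In-volume dose difference (low)"

    def test_hot_delivery_is_in_volume_high(self):
        r = self._oot(ptv_global_diff_pct=-10.0)
        mode, _ = classify_failure_mode(r)
        assert mode == "In-volume dose difference (high)"

    def test_non_uniform_displacement_is_other_shift(self):
        r = self._oot(edge_displacements={"LR": (2.5, -2.5)})
        mode, _ = classify_failure_mode(r)
        assert mode == "Other shift/misalignment"

    def test_outfield_excess_mode(self):
        r = self._oot(ptv_global_diff_pct=0.2, outfield_excess_pct=20.0)
        mode, _ = classify_failure_mode(r)
        assert mode == "Out of field dose (high)"

    def test_passing_plan_rejected(self):
        r = classify_outcome(_metrics(), "soft_tissue")
        with pytest.raises(ValueError, match="out-of-tolerance"):
            classify_failure_mode(r)


class TestCohortAggregation:
    def test_outcome_percentages_from_printed_counts(self):
        # out-of-tolerance tallies of the three audit cases
        assert percentages_from_counts({"oot": 10, "pass": 271})["oot"] == 3.6
        assert percentages_from_counts({"oot": 23, "pass": 215})["oot"] == 9.7
        assert percentages_from_counts({"oot": 27, "pass": 236})["oot"] == 10.3
        assert percentages_from_counts({"pass": 271, "oot": 10})["pass"] == 96.4

    def test_failure_mode_shares_over_60_failures(self):
        counts = dict(
            zip(
                (
                    "IGRT mismatch",
                    "In-volume dose difference (low)",
                    "In-volume dose difference (high)",
                    "Other shift/misalignment",
                    "Out of field dose (high)",
                    "Fusion of structure set to planning CT",
                    "Dose calculation grid size",
                ),
                (22, 13, 12, 6, 5, 1, 1),
            )
        )
        pct = percentages_from_counts(counts)
        assert pct["IGRT mismatch"] == 36.7
        assert pct["In-volume dose difference (high)"] == 20.0
        assert pct["Other shift/misalignment"] == 10.0
        assert pct["Out of field dose (high)"] == 8.3
        assert pct["Fusion of structure set to planning CT"] == 1.7
        # 13/60 rounds half-up to 21.7
        assert pct["In-volume dose difference (low)"] == 21.7

    def test_round_half_up_convention(self):
        assert round_half_up(3.55) == 3.6
        assert round_half_up(3.649) == 3.6
        assert round_half_up(96.45) == 96.5

    def test_single_optimal_plan_is_100pct(self):
        result = classify_outcome(_metrics(), "soft_tissue")
        summary = aggregate_cohort([result])
        assert summary.outcome_pct["soft_tissue"]["optimal"] == 100.0

    def test_counts_conserved_across_partition(self):
        rng = np.random.default_rng(0)
        results = []
        for _ in range(40):
            gamma = rng.uniform(85, 100)
            results.append(classify_outcome(_metrics(gamma=gamma), "soft_tissue"))
        summary = aggregate_cohort(results)
        assert sum(summary.outcome_counts["soft_tissue"].values()) == 40
        assert summary.n_total == 40

    def test_unknown_case_rejected(self):
        r = classify_outcome(_metrics(), "soft_tissue")
        r.case_id = "brain"
        with pytest.raises(ValueError, match="unknown case"):
            aggregate_cohort([r])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_cohort([])


class TestCompareSeries:
    def test_identical_series(self):
        out = compare_series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0 and out["p"] == 1.0 and not out["significant"]

    def test_hand_computed_pooled_t(self):
        out = compare_series([1, 2, 3], [4, 5, 6])
        assert out["t"] == pytest.approx(-3.674, abs=1e-3)
        assert out["p"] == pytest.approx(0.0213, abs=5e-4)
        assert out["significant"]

    def test_zero_variance_equal_means_degenerate(self):
        out = compare_series([2.0, 2.0], [2.0, 2.0])
        assert out["degenerate"] and out["p"] == 1.0

    def test_zero_variance_unequal_means_flagged(self):
        out = compare_series([2.0, 2.0], [3.0, 3.0])
        assert out["degenerate"] and out["significant"]

    def test_significance_strictly_below_alpha(self):
        assert not compare_series([0, 1, 2], [0.5, 1.5, 2.4])["significant"]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            compare_series([1.0], [2.0, 3.0])
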