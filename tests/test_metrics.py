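import numpy as np
import pytest

from sbrtaudit.cases import get_case
from sbrtaudit.grid import DosePlane
from sbrtaudit.metrics import (
    GammaParams,
    conformity_indices,
    gamma_global,
    gamma_oracle,
    interface_dta,
    point_dose_diff,
    profile_dta,
    ptv_region_from_isodose,
    region_dose_stats,
)
from sbrtaudit.synthetic import (
    GEOMETRY,
    OUT_OF_FIELD_FLOOR,
    PLATEAU_FRACTION,
    PerturbationSpec,
    child_rng,
    isodose_radius,
    perturb_dose,
)

from conftest import case_setup


def small_setup(case_id="soft_tissue"):
    return case_setup(case_id, (101, 101), 0.5)


def upsampled(plane, pitch):
    n = int(round((plane.x[-1] - plane.x[0]) / pitch)) + 1
    x = plane.x[0] + pitch * np.arange(n)
    y = plane.y[0] + pitch * np.arange(n)
    X, Y = np.meshgrid(x, y)
    return DosePlane(plane.sample(X, Y), pitch, (x[0], y[0]))


def seeded_pair(seed, case_id="soft_tissue"):
    """A planned/perturbed measured pair with seeded realistic errors."""
    phantom, case, planned = small_setup(case_id)
    rng = child_rng(seed, 77)
    spec = PerturbationSpec(
        shift=(rng.uniform(-2, 2), rng.uniform(-2, 2)),
        global_scale=rng.uniform(0.94, 1.08),
        noise_sigma=0.005,
        seed=seed,
    )
    measured = perturb_dose(planned, spec, phantom.structures, case.prescription_per_fraction)
    return planned, measured, case.prescription_per_fraction


class TestGamma:
    def test_identical_planes_all_zero_and_100pct(self):
        _, case, planned = small_setup()
        p = GammaParams(normalization_gy=case.prescription_per_fraction)
        g = gamma_global(planned, planned.copy(), p)
        assert g.pass_rate == 100.0
        assert np.nanmax(g.gamma_map) == 0.0

    def test_flat_plateau_10pct_offset_fails_everywhere(self):
        p = GammaParams(normalization_gy=10.0)
        planned = DosePlane(np.full((81, 81), 10.0), 0.5, (-20, -20))
        measured = DosePlane(planned.values / 1.10, 0.5, (-20, -20))
        g = gamma_global(planned, measured, p)
        assert g.pass_rate == 0.0

    def test_1p5mm_translation_passes_2mm_criterion(self):
        _, case, planned = small_setup()
        measured = perturb_dose(planned, PerturbationSpec(shift=(1.5, 0.0)))
        p = GammaParams(normalization_gy=case.prescription_per_fraction)
        assert gamma_global(planned, measured, p).pass_rate == 100.0

    def test_hot_pixel_gamma_is_offset_over_criterion(self):
        vals = np.full((61, 61), 10.0)
        meas = vals.copy()
        meas[30, 30] = 12.0  # +20% of normalization on a flat background
        p = GammaParams(normalization_gy=10.0)
        g = gamma_oracle(DosePlane(vals, 0.5, (-15, -15)), DosePlane(meas, 0.5, (-15, -15)), p)
        assert g.gamma_map[30, 30] == pytest.approx(0.20 / 0.05, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_aligned_lattices(self, seed):
        planned, measured, rx = seeded_pair(seed)
        # engine on the grid-pitch lattice vs node-exhaustive oracle
        p = GammaParams(normalization_gy=rx, subsample_mm=0.5)
        g1 = gamma_global(planned, measured, p)
        g2 = gamma_oracle(planned, measured, p)
        assert np.nanmax(np.abs(g1.gamma_map - g2.gamma_map)) <= 0.02
        # engine at 0.25 mm vs oracle over the upsampled reference nodes
        p = GammaParams(normalization_gy=rx, subsample_mm=0.25)
        g3 = gamma_global(planned, measured, p)
        g4 = gamma_oracle(upsampled(planned, 0.25), measured, p, max_nodes=401)
        assert np.nanmax(np.abs(g3.gamma_map - g4.gamma_map)) <= 0.02

    @pytest.mark.parametrize("seed", range(0, 20, 2))
    def test_pass_rate_monotone_in_criteria(self, seed):
        # per-pixel gamma never increases when either criterion is widened;
        # compare over the pixels valid under both (the search radius, and
        # hence the boundary-invalid band, grows with the DTA criterion)
        planned, measured, rx = seeded_pair(seed)
        base = gamma_global(planned, measured, GammaParams(normalization_gy=rx))
        wider_dose = gamma_global(
            planned, measured, GammaParams(normalization_gy=rx, dose_criterion=0.07)
        )
        wider_dta = gamma_global(
            planned, measured, GammaParams(normalization_gy=rx, dta_criterion_mm=3.0)
        )
        assert wider_dose.pass_rate >= base.pass_rate
        for wider in (wider_dose, wider_dta):
            common = np.isfinite(base.gamma_map) & np.isfinite(wider.gamma_map)
            pass_base = np.mean(base.gamma_map[common] <= 1.0)
            pass_wider = np.mean(wider.gamma_map[common] <= 1.0)
            assert pass_wider >= pass_base
            assert np.all(wider.gamma_map[common] <= base.gamma_map[common] + 1e-9)

    def test_invariant_under_common_translation(self):
        planned, measured, rx = seeded_pair(3)
        p = GammaParams(normalization_gy=rx)
        g0 = gamma_global(planned, measured, p)
        shift = PerturbationSpec(shift=(1.0, 0.5))
        ps = perturb_dose(planned, shift)
        ms = perturb_dose(measured, shift)
        g1 = gamma_global(ps, ms, p)
        # compare away from the moved boundary; (1.0, 0.5) mm = (2, 1) pixels
        a, b = g0.gamma_map[20:-20, 20:-20], g1.gamma_map[21:-19, 22:-18]
        sel = np.isfinite(a) & np.isfinite(b)
        assert np.nanmax(np.abs(a[sel] - b[sel])) < 0.02

    def test_threshold_excludes_low_dose_pixels(self):
        _, case, planned = small_setup()
        p = GammaParams(normalization_gy=case.prescription_per_fraction)
        g = gamma_global(planned, planned.copy(), p)
        low = planned.values < p.threshold * p.normalization_gy
        assert np.all(np.isnan(g.gamma_map[low]))

    def test_coarse_subsample_rejected(self):
        planned, measured, rx = seeded_pair(0)
        with pytest.raises(ValueError, match="subsample"):
            gamma_global(planned, measured, GammaParams(normalization_gy=rx, subsample_mm=1.5))

    def test_empty_valid_region_rejected(self):
        p = GammaParams(normalization_gy=10.0)
        zero = DosePlane(np.zeros((61, 61)), 0.5, (-15, -15))
        with pytest.raises(ValueError, match="no valid"):
            gamma_global(zero, zero.copy(), p)

    def test_oracle_refuses_large_grids(self):
        phantom, case, planned = case_setup("soft_tissue")
        p = GammaParams(normalization_gy=case.prescription_per_fraction)
        with pytest.raises(ValueError, match="restricted"):
            gamma_oracle(planned, planned.copy(), p)


class TestProfileDTA:
    def test_identical_planes_zero_dta(self):
        _, case, planned = small_setup()
        r = profile_dta(planned, planned.copy(), "LR", case.prescription_per_fraction)
        assert r.mean_mm == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("shift", [0.5, 1.0, 2.0, 3.0])
    def test_translation_recovered_as_signed_dta(self, shift):
        phantom, case, planned = case_setup("soft_tissue")
        measured = perturb_dose(planned, PerturbationSpec(shift=(0.0, shift)))
        r = profile_dta(planned, measured, "AP", case.prescription_per_fraction)
        # planned - measured convention: a +s shift reads as -s
        assert r.mean_mm == pytest.approx(-shift, abs=0.1)

    def test_scale_moves_crossings_by_dose_over_gradient(self):
        phantom, case, planned = case_setup("soft_tissue")
        rx = case.prescription_per_fraction
        measured = perturb_dose(planned, PerturbationSpec(global_scale=1.05))
        r = profile_dta(planned, measured, "LR", rx)
        # analytic: crossing shift = dD / gradient at the 70% level
        level = 0.7 * rx
        s = 3.0 / (2 * np.log(4.0))
        f = (0.7 - OUT_OF_FIELD_FLOOR) / (PLATEAU_FRACTION - OUT_OF_FIELD_FLOOR)
        grad = (PLATEAU_FRACTION - OUT_OF_FIELD_FLOOR) * rx * f * (1 - f) / s
        expected = 0.05 * level / grad
        assert r.edges["low"] == pytest.approx(expected, abs=0.03)
        assert r.edges["high"] == pytest.approx(-expected, abs=0.03)

    def test_no_crossing_reports_side(self):
        _, case, planned = small_setup()
        flat = DosePlane(np.zeros_like(planned.values), planned.spacing, planned.origin)
        with pytest.raises(ValueError, match="measured"):
            profile_dta(planned, flat, "LR", case.prescription_per_fraction)

    def test_spine_interface_shift_recovered(self):
        phantom, case, planned = case_setup("spine")
        rx = case.prescription_per_fraction
        measured = perturb_dose(planned, PerturbationSpec(shift=(0.0, 1.0)))
        r = interface_dta(planned, measured, GEOMETRY["spine"]["cord_centre"], rx)
        assert abs(r["max_ap_mm"]) == pytest.approx(1.0, abs=0.1)


class TestDoseDifferences:
    def test_point_diff_printed_formula(self):
        r = point_dose_diff(10.5, 10.0, 15.0)
        assert r.local_pct == pytest.approx(5.0, abs=1e-12)
        assert r.global_pct == pytest.approx(100 * 0.5 / 15.0, abs=1e-9)

    def test_point_diff_zero_when_equal(self):
        r = point_dose_diff(10.0, 10.0, 15.0)
        assert r.local_pct == 0.0 and r.global_pct == 0.0

    def test_region_local_diff_for_3pct_cold_delivery(self):
        _, case, planned = small_setup()
        rx = case.prescription_per_fraction
        ptv = ptv_region_from_isodose(planned, rx)
        measured = planned.copy()
        measured.values[ptv] *= 0.97
        r = region_dose_stats(planned, measured, ptv, rx)
        assert r.local_pct == pytest.approx(100 * (1 / 0.97 - 1), abs=1e-6)

    def test_region_locality_of_outfield_scaling(self):
        phantom, case, planned = small_setup("spine")
        rx = case.prescription_per_fraction
        measured = perturb_dose(
            planned, PerturbationSpec(outfield_scale=1.2), phantom.structures, rx
        )
        ptv = ptv_region_from_isodose(planned, rx)
        r = region_dose_stats(planned, measured, ptv, rx)
        assert r.global_pct == pytest.approx(0.0, abs=1e-9)

    def test_empty_region_rejected(self):
        _, case, planned = small_setup()
        with pytest.raises(ValueError, match="empty"):
            region_dose_stats(planned, planned, np.zeros_like(planned.values, bool), 1.0)


class TestConformity:
    def test_isodose_matching_ptv_gives_unity(self):
        _, case, planned = small_setup()
        rx = case.prescription_per_fraction
        ptv = ptv_region_from_isodose(planned, rx)
        ci100, _ = conformity_indices(planned, ptv, rx)
        assert ci100 == 1.0

    def test_circle_area_ratios_match_analytic_radii(self):
        phantom, case, planned = case_setup("soft_tissue")
        rx = case.prescription_per_fraction
        ci100, ci50 = conformity_indices(planned, phantom.structures["ptv"], rx)
        r100 = isodose_radius("soft_tissue", 1.0)
        r50 = isodose_radius("soft_tissue", 0.5)
        assert ci100 == pytest.approx((r100 / 12.5) ** 2, rel=0.02)
        assert ci50 == pytest.approx((r50 / 12.5) ** 2, rel=0.02)

    @pytest.mark.parametrize("case_id", ["soft_tissue", "spine", "lung"])
    def test_default_plans_within_ci_limits(self, case_id):
        phantom, case, planned = case_setup(case_id)
        ci100, ci50 = conformity_indices(
            planned, phantom.structures["ptv"], case.prescription_per_fraction
        )
        assert ci100 <= 1.2
        assert ci50 <= 5.0
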