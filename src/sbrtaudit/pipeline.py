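"""End-to-end simulated audit measurements: plan -> delivery -> film -> score.

One call to :func:`simulate_audit` reproduces the whole measurement chain
for one plan of one case:

1. build the phantom film plane and the analytic planned dose;
2. perturb the delivered dose with a known injected error;
3. expose and scan a synthetic film (forward response, darkening, scanner
   noise, a per-session scanner scale drift), fit the calibration, run the
   check-film QC (with automatic rescans when the 5% limit trips) and
   convert the scan back to absolute dose;
4. place the film at a random scanner offset and register it back to the
   plan grid from the fiducial cut-outs, with a dual-observer check;
5. apply medium corrections tailored to the reporting mode;
6. compute gamma / DTA / point and region dose metrics and classify the
   outcome and failure mode.

Every stochastic step derives from the single plan seed, so a plan is fully
reproducible from ``(case_id, perturbation, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cases import CaseDefinition, get_case
from .film import (
    CheckFilmPair,
    RescanRequiredError,
    check_film_qc,
    fit_calibration,
    scan_to_dose,
)
from .grid import DosePlane
from .kmed import KmedTable, PointCorrectionSet, apply_kmed_map, correct_point_reading
from .metrics import (
    GammaParams,
    conformity_indices,
    cord_roi,
    gamma_global,
    interface_dta,
    point_dose_diff,
    profile_dta,
    ptv_region_from_isodose,
    region_dose_stats,
    verify_plan_constraints,
)
from .registration import LandmarkSet, RigidTransform2D, fit_rigid, observer_agreement, resample_to_plan
from .scoring import AuditResult, ScoringThresholds, classify_failure_mode, classify_outcome
from .synthetic import (
    GEOMETRY,
    FilmForwardModel,
    PerturbationSpec,
    PhantomPlane,
    child_rng,
    make_calibration_dataset,
    make_phantom_plane,
    make_planned_dose,
    perturb_dose,
    render_film_scan,
)

__all__ = ["MeasurementConfig", "simulate_audit", "simulate_cohort", "compute_metrics"]


@dataclass(frozen=True)
class MeasurementConfig:
    """Nuisance parameters of the simulated measurement process."""

    film_chain: bool = True  # run the netOD forward/inverse chain
    scan_registration: bool = True  # random scanner placement + registration
    scan_delay_hours: float = 36.0
    session_scale_sigma: float = 0.0223  # scanner drift; ~2.5% of scans trip the 5% QC
    check_film_noise: float = 0.003  # relative, per check film
    point_noise: float = 0.015  # microDiamond repeatability, relative
    observer_noise_mm: float = 0.05  # landmark digitization noise per observer
    scan_offset_mm: float = 2.0  # max random film placement offset
    scan_rotation_deg: float = 1.0
    max_rescans: int = 3
    grid_shape: tuple[int, int] = (200, 200)
    spacing_mm: float = 0.5


_POINTS = {  # in-PTV detector points, plateau regions of each case
    "soft_tissue": (0.0, 0.0),
    "spine": (0.0, -10.0),  # trabecular bone anterior to the cord
    "lung": (0.0, 0.0),
}


def _film_measurement(
    delivered_film_dose: DosePlane,
    model: FilmForwardModel,
    cfg: MeasurementConfig,
    seed: int,
):
    """Scan, QC and convert the film; returns the dose plane and QC record."""
    calmodel = fit_calibration(
        make_calibration_dataset(model), darkening=model.darkening
    )
    rng = child_rng(seed, 401)
    qc = None
    for attempt in range(cfg.max_rescans + 1):
        session = 1.0 + rng.normal(0.0, cfg.session_scale_sigma)
        chamber = (10.0, 15.0)
        film = tuple(
            c * session * (1.0 + rng.normal(0.0, cfg.check_film_noise)) for c in chamber
        )
        qc = check_film_qc(CheckFilmPair(chamber_doses=chamber, film_doses=film))
        if qc.within_limit:
            break
    if qc is None or not qc.within_limit:
        raise RescanRequiredError("check-film QC failed after all rescans")
    scan = render_film_scan(
        delivered_film_dose, model, cfg.scan_delay_hours, seed=seed
    )
    # scanner session drift: multiplicative on the recorded response
    drift = replace(scan, netod=scan.netod.copy())
    for ch in range(3):
        dose_equiv = model.dose_from_netod(
            np.clip(scan.netod[ch] / model.darkening_factor(ch, scan.scan_delay_hours), 0, None), ch
        )
        drift.netod[ch] = model.netod(
            np.clip(dose_equiv * session, 0, None), ch, scan.scan_delay_hours
        )
    measured = scan_to_dose(drift, calmodel, qc)
    return measured, {"qc_scale_factor": qc.scale_factor, "rescans": attempt}


def _scanner_placement(
    measured: DosePlane,
    phantom: PhantomPlane,
    cfg: MeasurementConfig,
    seed: int,
):
    """Film placed at a random scanner pose, then registered back."""
    rng = child_rng(seed, 501)
    angle = rng.uniform(-cfg.scan_rotation_deg, cfg.scan_rotation_deg)
    offset = rng.uniform(-cfg.scan_offset_mm, cfg.scan_offset_mm, size=2)
    pose = RigidTransform2D(angle, (float(offset[0]), float(offset[1])))

    # the film content as seen in scanner coordinates: plan point p appears
    # at pose(p), so the scanner image is measured(pose^-1(q))
    scanner_plane = resample_to_plan(measured, pose, measured)

    transforms = []
    for obs in (1, 2):
        noisy = phantom.fiducials + rng.normal(0.0, cfg.observer_noise_mm, size=phantom.fiducials.shape)
        film_pts = pose.apply(noisy)
        transforms.append(
            fit_rigid(LandmarkSet(film=film_pts, plan=phantom.fiducials, observer=f"observer{obs}"))
        )
    hx = abs(measured.x[-1] - measured.x[0]) / 2
    hy = abs(measured.y[-1] - measured.y[0]) / 2
    discrepancy, agreed = observer_agreement(transforms[0], transforms[1], (hx, hy))
    registered = resample_to_plan(scanner_plane, transforms[0], measured)
    return registered, {
        "observer_discrepancy_mm": discrepancy,
        "observers_agree": agreed,
        "registration_rms_mm": transforms[0].rms_residual_mm,
    }


def compute_metrics(
    planned: DosePlane,
    measured: DosePlane,
    phantom: PhantomPlane,
    case: CaseDefinition,
    point_measured: float | None = None,
    gamma_params: GammaParams | None = None,
) -> dict:
    """All scored and diagnostic metrics for one measured plane."""
    rx = case.prescription_per_fraction
    p = gamma_params or GammaParams(normalization_gy=rx)
    metrics: dict = {}

    g = gamma_global(planned, measured, p)
    metrics["gamma_pass_rate_pct"] = g.pass_rate

    edge_disp = {}
    if case.case_id == "spine":
        iface = interface_dta(planned, measured, GEOMETRY["spine"]["cord_centre"], rx)
        metrics["dta_max_interface_ap_mm"] = iface["max_ap_mm"]
        metrics["dta_mean_interface_lr_mm"] = iface["mean_lr_mm"]
        for axis in ("LR", "AP"):
            r = profile_dta(planned, measured, axis, rx, line_mm=0.0)
            edge_disp[axis] = (r.edges.get("low", 0.0), r.edges.get("high", 0.0))
    else:
        for axis in ("LR", "AP"):
            r = profile_dta(planned, measured, axis, rx, line_mm=0.0)
            edge_disp[axis] = (r.edges.get("low", 0.0), r.edges.get("high", 0.0))
            metrics[f"dta_mean_{axis.lower()}_mm"] = r.mean_mm
        if case.case_id == "lung":
            # the film pin obstructs the left-right isodose; AP only is scored
            metrics.pop("dta_mean_lr_mm", None)
    metrics["edge_displacements"] = edge_disp

    point = _POINTS[case.case_id]
    plan_at_point = float(planned.sample(*point))
    if point_measured is None:
        point_measured = float(measured.sample(*point))
    pd = point_dose_diff(plan_at_point, point_measured, rx)
    metrics["point_diff_local_pct"] = pd.local_pct
    metrics["point_diff_global_pct"] = pd.global_pct

    ptv = ptv_region_from_isodose(planned, rx)
    reg = region_dose_stats(planned, measured, ptv, rx, region="PTV")
    metrics["ptv_global_diff_pct"] = reg.global_pct
    metrics["ptv_local_diff_pct"] = reg.local_pct
    sel = ptv & np.isfinite(measured.values) & (planned.values > 0)
    metrics["ptv_scale_recovered"] = float(
        np.mean(measured.values[sel] / planned.values[sel])
    )

    outfield = (planned.values < 0.5 * rx) & (planned.values >= p.threshold * rx)
    outfield &= np.isfinite(measured.values)
    if outfield.any():
        metrics["outfield_excess_pct"] = float(
            100.0 * np.mean(measured.values[outfield] - planned.values[outfield]) / rx
        )
    if case.case_id == "spine":
        roi = cord_roi(planned, GEOMETRY["spine"]["cord_centre"])
        cord = region_dose_stats(planned, measured, roi, rx, region="cord_ROI")
        metrics["cord_roi_local_diff_pct"] = cord.local_pct
        metrics["cord_roi_global_diff_pct"] = cord.global_pct

    ci100, ci50 = conformity_indices(planned, phantom.structures["ptv"], rx)
    metrics["ci100"] = ci100
    metrics["ci50"] = ci50
    return metrics


def simulate_audit(
    case_id: str,
    perturbation: PerturbationSpec | None = None,
    seed: int = 0,
    config: MeasurementConfig = MeasurementConfig(),
    film_model: FilmForwardModel = FilmForwardModel(),
    kmed_table: KmedTable | None = None,
    thresholds: ScoringThresholds = ScoringThresholds(),
    classify_failures: bool = True,
) -> AuditResult:
    """Simulate one complete audit measurement and score it."""
    case = get_case(case_id)
    phantom = make_phantom_plane(case_id, config.grid_shape, config.spacing_mm)
    planned = make_planned_dose(phantom, case)
    spec = perturbation or PerturbationSpec(seed=seed)
    if spec.seed != seed:
        spec = replace(spec, seed=seed)
    delivered = perturb_dose(
        planned, spec, phantom.structures, case.prescription_per_fraction
    )
    table = kmed_table or KmedTable.default()
    extras: dict = {"injected_mode": spec.injected_mode, "seed": seed}

    if config.film_chain:
        # the film responds to dose in its local medium; divide the embedded
        # correction out so the corrector restores the reported quantity
        factor = apply_kmed_map(
            DosePlane(np.ones(planned.shape), planned.spacing, planned.origin),
            phantom.materials, table, case.reporting_mode, case_id,
        ).values
        film_true = replace(delivered, values=delivered.values / factor)
        measured, qc_info = _film_measurement(film_true, film_model, config, seed)
        extras.update(qc_info)
    else:
        measured = delivered.copy()

    if config.scan_registration:
        measured, reg_info = _scanner_placement(measured, phantom, config, seed)
        extras.update(reg_info)

    if config.film_chain:
        measured = apply_kmed_map(
            measured, phantom.materials, table, case.reporting_mode, case_id
        )

    # independent point-detector reading with its own corrections
    rng = child_rng(seed, 601)
    point = _POINTS[case_id]
    corrections = PointCorrectionSet()
    true_point = float(delivered.sample(*point))
    raw = true_point / corrections.combined * (1.0 + rng.normal(0.0, config.point_noise))
    point_measured = correct_point_reading(raw, corrections)

    metrics = compute_metrics(planned, measured, phantom, case, point_measured)
    metrics.update(extras)
    result = classify_outcome(metrics, case_id, thresholds)
    if classify_failures and result.outcome == "out_of_tolerance":
        classify_failure_mode(result, thresholds)
    return result


def simulate_cohort(
    plans: list[tuple[str, PerturbationSpec | None]],
    seed: int = 0,
    config: MeasurementConfig = MeasurementConfig(),
    **kwargs,
) -> list[AuditResult]:
    """Simulate a cohort of plans; plan i uses child seed (seed, i)."""
    results = []
    for i, (case_id, spec) in enumerate(plans):
        plan_seed = int(child_rng(seed, 701, i).integers(0, 2**31 - 1))
        results.append(
            simulate_audit(case_id, spec, seed=plan_seed, config=config, **kwargs)
        )
    return results


def plan_constraint_report(case_id: str, grid_shape=(200, 200), spacing=0.5) -> dict:
    """Constraint verification of the default planned dose for a case."""
    phantom = make_phantom_plane(case_id, grid_shape, spacing)
    case = get_case(case_id)
    planned = make_planned_dose(phantom, case)
    return verify_plan_constraints(planned, phantom, case)
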