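"""Quantitative audit metrics: global gamma, isodose DTA, dose differences.

The gamma index blends dose difference and distance-to-agreement:

    gamma(m) = min over r in the planned distribution of
               sqrt( |r - r_m|^2 / dta^2  +  (D_p(r) - D_m(r_m))^2 / delta^2 )

evaluated at every measured-film pixel above the low-dose threshold, with
``delta`` a fixed fraction of the per-fraction prescription (a *global*
criterion) and the planned dose interpolated at sub-pixel pitch within a
bounded search radius.  ``gamma_oracle`` is an independent brute-force
evaluation over planned grid nodes used to validate the production engine.

The 1D distance-to-agreement compares the positions where planned and
measured dose profiles cross the 70% isodose level, signed planned minus
measured; the spine variant scores the maximum across anterior-posterior
profiles through the PTV/spinal-cord interface.  Dose differences follow the
audit definitions: local ``(planned - measured)/measured`` and global
``(planned - measured)/prescription per fraction``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import DosePlane, circle_mask

__all__ = [
    "GammaParams",
    "GammaResult",
    "DTAResult",
    "DoseDiffResult",
    "gamma_global",
    "gamma_oracle",
    "profile_dta",
    "interface_dta",
    "point_dose_diff",
    "region_dose_stats",
    "conformity_indices",
    "ptv_region_from_isodose",
    "verify_plan_constraints",
]


# ---------------------------------------------------------------------------
# gamma
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaParams:
    """Global gamma criteria; defaults are the audit's 5%/2 mm, 10% threshold."""

    dose_criterion: float = 0.05  # fraction of normalization
    dta_criterion_mm: float = 2.0
    threshold: float = 0.10  # of normalization, applied to measured dose
    normalization_gy: float = 1.0  # per-fraction prescription
    search_radius_factor: float = 3.0
    subsample_mm: float = 0.2

    def __post_init__(self) -> None:
        for v in (self.dose_criterion, self.dta_criterion_mm, self.threshold,
                  self.normalization_gy, self.search_radius_factor, self.subsample_mm):
            if v <= 0:
                raise ValueError("gamma parameters must be positive")
        if self.threshold >= 1:
            raise ValueError("threshold must be below 1")


@dataclass
class GammaResult:
    gamma_map: np.ndarray  # NaN where invalid (below threshold / boundary)
    pass_rate: float  # % of valid pixels with gamma <= 1
    n_valid: int
    params: GammaParams


def _gamma_validity(planned: DosePlane, measured: DosePlane, p: GammaParams) -> np.ndarray:
    """Valid evaluation pixels: above threshold, finite, search disc in-grid.

    The measured plane must already be registered into the plan frame; the
    planned grid may be finer (it is interpolated / searched), but must
    enclose every measured search disc.
    """
    valid = np.isfinite(measured.values)
    valid &= measured.values >= p.threshold * p.normalization_gy
    r_max = p.search_radius_factor * p.dta_criterion_mm
    X, Y = measured.meshgrid()
    xmin, xmax, ymin, ymax = planned.extent
    valid &= (X - r_max >= xmin - 1e-9) & (X + r_max <= xmax + 1e-9)
    valid &= (Y - r_max >= ymin - 1e-9) & (Y + r_max <= ymax + 1e-9)
    return valid


def _finish(gamma2: np.ndarray, valid: np.ndarray, p: GammaParams) -> GammaResult:
    gmap = np.full(valid.shape, np.nan)
    gmap[valid] = np.sqrt(gamma2)
    n_valid = int(valid.sum())
    passing = np.sum(gamma2 <= 1.0 + 1e-12)
    return GammaResult(
        gamma_map=gmap,
        pass_rate=100.0 * passing / n_valid,
        n_valid=n_valid,
        params=p,
    )


def gamma_global(planned: DosePlane, measured: DosePlane, p: GammaParams) -> GammaResult:
    """Global 2D gamma of a measured plane against the plan.

    Gamma is evaluated at measured pixels (the audit scores the measurement);
    the planned distribution is interpolated bilinearly on a
    ``subsample_mm`` offset lattice inside a ``search_radius_factor * dta``
    disc.  Offsets are visited in order of increasing radius with early
    termination once no pixel can improve, which is exact.
    """
    if p.subsample_mm > p.dta_criterion_mm / 2:
        raise ValueError("subsample pitch coarser than dta/2")
    valid = _gamma_validity(planned, measured, p)
    if not valid.any():
        raise ValueError("no valid pixels above the dose threshold")

    delta = p.dose_criterion * p.normalization_gy
    dta = p.dta_criterion_mm
    r_max = p.search_radius_factor * dta

    X, Y = measured.meshgrid()
    xm = X[valid]
    ym = Y[valid]
    dm = measured.values[valid]

    k = int(math.floor(r_max / p.subsample_mm))
    off = p.subsample_mm * np.arange(-k, k + 1)
    ox, oy = np.meshgrid(off, off)
    rr = np.hypot(ox, oy).ravel()
    keep = rr <= r_max + 1e-12
    ox, oy, rr = ox.ravel()[keep], oy.ravel()[keep], rr[keep]
    order = np.argsort(rr, kind="stable")
    ox, oy, rr = ox[order], oy[order], rr[order]

    interp = planned.interpolator()
    gamma2 = np.full(xm.shape, np.inf)
    for dx, dy, r in zip(ox, oy, rr):
        r2 = (r / dta) ** 2
        improvable = gamma2 > r2
        if not improvable.any():
            break
        idx = np.nonzero(improvable)[0]
        pd = interp(np.stack([ym[idx] + dy, xm[idx] + dx], axis=-1))
        cand = r2 + ((pd - dm[idx]) / delta) ** 2
        cand = np.where(np.isfinite(cand), cand, np.inf)
        gamma2[idx] = np.minimum(gamma2[idx], cand)
    return _finish(gamma2, valid, p)


def gamma_oracle(planned: DosePlane, measured: DosePlane, p: GammaParams,
                 max_nodes: int = 101) -> GammaResult:
    """Brute-force gamma over planned grid nodes, for validation only.

    Evaluates every planned node inside the same bounded search radius with
    no interpolation, subsampling or early termination.  Restricted to small
    grids.
    """
    if max(planned.shape) > max_nodes or max(measured.shape) > max_nodes:
        raise ValueError(f"oracle restricted to grids of at most {max_nodes} nodes per side")
    valid = _gamma_validity(planned, measured, p)
    if not valid.any():
        raise ValueError("no valid pixels above the dose threshold")

    delta = p.dose_criterion * p.normalization_gy
    dta = p.dta_criterion_mm
    r_max = p.search_radius_factor * dta

    X, Y = measured.meshgrid()
    xm, ym, dm = X[valid], Y[valid], measured.values[valid]
    px, py, pv = planned.x, planned.y, planned.values

    gamma2 = np.empty(xm.shape)
    for i in range(xm.size):
        jx0 = np.searchsorted(px, xm[i] - r_max, side="left")
        jx1 = np.searchsorted(px, xm[i] + r_max, side="right")
        jy0 = np.searchsorted(py, ym[i] - r_max, side="left")
        jy1 = np.searchsorted(py, ym[i] + r_max, side="right")
        nx = px[jx0:jx1] - xm[i]
        ny = py[jy0:jy1] - ym[i]
        r2 = (ny[:, None] ** 2 + nx[None, :] ** 2) / dta**2
        dd2 = ((pv[jy0:jy1, jx0:jx1] - dm[i]) / delta) ** 2
        g2 = r2 + dd2
        g2 = np.where(r2 <= (r_max / dta) ** 2 + 1e-12, g2, np.inf)
        gamma2[i] = np.min(g2)
    return _finish(gamma2, valid, p)


# ---------------------------------------------------------------------------
# 1D isodose DTA
# ---------------------------------------------------------------------------


@dataclass
class DTAResult:
    """Signed isodose-crossing displacements (planned minus measured), mm."""

    axis: str  # "LR" or "AP"
    level_fraction: float
    edges: dict = field(default_factory=dict)  # edge label -> displacement mm
    mean_mm: float = float("nan")
    max_mm: float = float("nan")  # signed value with the largest magnitude
    pairs: list = field(default_factory=list)  # all matched (planned, measured)


def _profile(plane: DosePlane, axis: str, line_mm: float):
    if axis == "LR":
        pos = plane.x
        vals = plane.sample(pos, np.full_like(pos, line_mm))
    elif axis == "AP":
        pos = plane.y
        vals = plane.sample(np.full_like(plane.y, line_mm), plane.y)
    else:
        raise ValueError("axis must be 'LR' or 'AP'")
    return pos, vals


def _crossings(pos: np.ndarray, vals: np.ndarray, level: float):
    """Linear-interpolated crossing positions with direction (+1 rising)."""
    out = []
    v = vals - level
    for i in range(len(v) - 1):
        a, b = v[i], v[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0 and b != 0.0:
            out.append((pos[i], 1 if b > 0 else -1))
        elif a < 0 < b or a > 0 > b:
            frac = a / (a - b)
            out.append((pos[i] + frac * (pos[i + 1] - pos[i]), 1 if b > a else -1))
    return out


def _match_crossings(planned_x, measured_x):
    """Pair same-direction crossings by proximity; unmatched are dropped."""
    pairs = []
    for direction in (+1, -1):
        pc = sorted(x for x, d in planned_x if d == direction)
        mc = sorted(x for x, d in measured_x if d == direction)
        if not pc or not mc:
            continue
        if len(pc) == len(mc):
            pairs.extend(zip(pc, mc))
        else:
            for x in pc:
                j = int(np.argmin([abs(x - m) for m in mc]))
                pairs.append((x, mc[j]))
    return pairs


def profile_dta(
    planned: DosePlane,
    measured: DosePlane,
    axis: str,
    prescription_per_fraction: float,
    level_fraction: float = 0.70,
    line_mm: float = 0.0,
) -> DTAResult:
    """1D DTA between planned and measured isodose crossings on one profile.

    The profile runs along ``axis`` at the fixed ``line_mm`` coordinate; the
    isodose level is ``level_fraction`` of the per-fraction prescription.
    The reported mean is over the two outermost field edges; displacements
    are signed planned minus measured.
    """
    level = level_fraction * prescription_per_fraction
    pos, pvals = _profile(planned, axis, line_mm)
    _, mvals = _profile(measured, axis, line_mm)
    pc = _crossings(pos, pvals, level)
    mc = _crossings(pos, mvals, level)
    if not pc or not mc:
        side = "planned" if not pc else "measured"
        raise ValueError(f"no {level_fraction:.0%} isodose crossing on the {side} profile")
    pairs = _match_crossings(pc, mc)
    result = DTAResult(axis=axis, level_fraction=level_fraction, pairs=pairs)

    rising = [x for x, d in pc if d == +1]
    falling = [x for x, d in pc if d == -1]
    edges = {}
    if rising:
        lo = min(rising)
        match = min(pairs, key=lambda pm: abs(pm[0] - lo))
        edges["low"] = match[0] - match[1]
    if falling:
        hi = max(falling)
        match = min(pairs, key=lambda pm: abs(pm[0] - hi))
        edges["high"] = match[0] - match[1]
    if not edges:
        raise ValueError("profile does not cross the isodose level on either edge")
    result.edges = edges
    result.mean_mm = float(np.mean(list(edges.values())))
    disp = [p - m for p, m in pairs]
    result.max_mm = float(disp[int(np.argmax(np.abs(disp)))])
    return result


def interface_dta(
    planned: DosePlane,
    measured: DosePlane,
    interface_centre: tuple[float, float],
    prescription_per_fraction: float,
    level_fraction: float = 0.70,
    span_mm: float = 6.0,
    window_mm: float = 8.0,
) -> dict:
    """Spine PTV/spinal-cord interface DTA.

    Scores anterior-posterior profiles sampled across ``span_mm`` around the
    cord centre, keeping only crossings within ``window_mm`` of the cord
    (the trough edges), and reports the signed displacement of largest
    magnitude; the left-right DTA at the interface is the mean over the two
    trough edges of the LR profile through the cord centre.
    """
    cx, cy = interface_centre
    level = level_fraction * prescription_per_fraction
    spacing = planned.spacing
    xs = cx + np.arange(-span_mm / 2, span_mm / 2 + 1e-9, spacing)

    worst = 0.0
    found = False
    for x0 in xs:
        pos, pvals = _profile_at(planned, "AP", x0)
        _, mvals = _profile_at(measured, "AP", x0)
        pc = [(p, d) for p, d in _crossings(pos, pvals, level) if abs(p - cy) <= window_mm]
        mc = [(p, d) for p, d in _crossings(pos, mvals, level) if abs(p - cy) <= window_mm]
        for p, m in _match_crossings(pc, mc):
            found = True
            if abs(p - m) > abs(worst):
                worst = p - m
    if not found:
        raise ValueError("no isodose crossing found at the PTV/cord interface")

    pos, pvals = _profile_at(planned, "LR", cy)
    _, mvals = _profile_at(measured, "LR", cy)
    pc = [(p, d) for p, d in _crossings(pos, pvals, level) if abs(p - cx) <= window_mm]
    mc = [(p, d) for p, d in _crossings(pos, mvals, level) if abs(p - cx) <= window_mm]
    pairs = _match_crossings(pc, mc)
    mean_lr = float(np.mean([p - m for p, m in pairs])) if pairs else float("nan")
    return {"max_ap_mm": float(worst), "mean_lr_mm": mean_lr}


def _profile_at(plane: DosePlane, axis: str, fixed_mm: float):
    """Profile along ``axis`` with the orthogonal coordinate fixed."""
    if axis == "LR":
        pos = plane.x
        vals = plane.sample(pos, np.full_like(pos, fixed_mm))
    else:
        pos = plane.y
        vals = plane.sample(np.full_like(plane.y, fixed_mm), plane.y)
    return pos, vals


# ---------------------------------------------------------------------------
# dose differences and conformity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseDiffResult:
    """Local and global percentage dose differences for a point or region."""

    local_pct: float  # (planned - measured)/measured * 100
    global_pct: float  # (planned - measured)/prescription per fraction * 100
    region: str = "point"


def point_dose_diff(
    planned_at_point: float,
    measured_corrected: float,
    prescription_per_fraction: float,
) -> DoseDiffResult:
    """Audit point-dose difference: (plan - measured)/measured (local)."""
    if measured_corrected <= 0:
        raise ValueError("measured point dose must be positive")
    diff = planned_at_point - measured_corrected
    return DoseDiffResult(
        local_pct=100.0 * diff / measured_corrected,
        global_pct=100.0 * diff / prescription_per_fraction,
        region="point",
    )


def region_dose_stats(
    planned: DosePlane,
    measured: DosePlane,
    mask: np.ndarray,
    prescription_per_fraction: float,
    region: str = "region",
) -> DoseDiffResult:
    """Mean local and global dose differences over a pixel region."""
    if not np.any(mask):
        raise ValueError("empty region mask")
    sel = mask & np.isfinite(measured.values) & np.isfinite(planned.values)
    sel &= measured.values > 0
    if not np.any(sel):
        raise ValueError("region contains no valid measured pixels")
    pdose = planned.values[sel]
    mdose = measured.values[sel]
    return DoseDiffResult(
        local_pct=float(100.0 * np.mean((pdose - mdose) / mdose)),
        global_pct=float(100.0 * np.mean(pdose - mdose) / prescription_per_fraction),
        region=region,
    )


def ptv_region_from_isodose(planned: DosePlane, prescription_per_fraction: float) -> np.ndarray:
    """The film-plane PTV: pixels bound by the planned prescription isodose."""
    mask = planned.values >= prescription_per_fraction
    if not mask.any():
        raise ValueError("planned plane has no prescription isodose region")
    return mask


def cord_roi(plane: DosePlane, centre: tuple[float, float], diameter_mm: float = 6.0) -> np.ndarray:
    """Circular ROI in the central part of the spinal cord."""
    return circle_mask(plane.shape, plane.spacing, plane.origin, centre, diameter_mm / 2.0)


def conformity_indices(
    planned: DosePlane,
    ptv_mask: np.ndarray,
    prescription_per_fraction: float,
) -> tuple[float, float]:
    """Planar CI100 and CI50: isodose area over PTV area.

    A 2D surrogate of the volumetric conformity index, evaluated on the film
    plane: ``CI_x = area(dose >= x% of prescription) / area(PTV)``.
    """
    ptv_area = int(np.count_nonzero(ptv_mask))
    if ptv_area == 0:
        raise ValueError("empty PTV mask")
    a100 = int(np.count_nonzero(planned.values >= prescription_per_fraction))
    a50 = int(np.count_nonzero(planned.values >= 0.5 * prescription_per_fraction))
    return a100 / ptv_area, a50 / ptv_area


# ---------------------------------------------------------------------------
# planning-constraint verification
# ---------------------------------------------------------------------------


def verify_plan_constraints(planned: DosePlane, phantom, case) -> dict:
    """Check a planned dose plane against its case's planning constraints.

    Evaluates per-fraction surrogates on the film plane: PTV coverage at the
    prescription isodose, the 110-140% max-dose window, CI100/CI50 limits and
    per-fraction OAR maxima.  Returns a report dict with an ``ok`` flag and
    the list of violated constraints.
    """
    rx = case.prescription_per_fraction
    ptv = phantom.structures["ptv"]
    violations = []

    coverage = float(np.mean(planned.values[ptv] >= rx))
    if coverage < case.coverage_requirement:
        violations.append(
            f"coverage {coverage:.3f} < required {case.coverage_requirement:.2f}"
        )
    dmax = float(np.max(planned.values))
    lo, hi = case.max_dose_window
    if not lo * rx <= dmax <= hi * rx:
        violations.append(f"max dose {dmax:.2f} Gy outside [{lo:.2f}, {hi:.2f}] x Rx")
    ci100, ci50 = conformity_indices(planned, ptv, rx)
    if ci100 > case.ci100_limit:
        violations.append(f"CI100 {ci100:.2f} > {case.ci100_limit}")
    if ci50 > case.ci50_limit:
        violations.append(f"CI50 {ci50:.2f} > {case.ci50_limit}")
    oar_max = {}
    for limit in case.oar_limits:
        mask = phantom.structures[limit.structure]
        per_fraction_limit = limit.max_gy / case.n_fractions
        m = float(np.max(planned.values[mask]))
        oar_max[limit.structure] = m
        if m > per_fraction_limit:
            violations.append(
                f"{limit.structure} max {m:.2f} Gy/fx > {per_fraction_limit:.2f} Gy/fx"
            )
    return {
        "ok": not violations,
        "violations": violations,
        "coverage": coverage,
        "max_dose_gy": dmax,
        "ci100": ci100,
        "ci50": ci50,
        "oar_max_gy": oar_max,
    }
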