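"""Digital phantom planes, planned doses, delivery perturbations and film scans.

This module emulates the three audit measurement set-ups so that every stage
of the analysis pipeline can be exercised with known ground truth:

* geometry — material masks and structures on the film plane for a 2.5 cm
  cylindrical soft-tissue PTV, a wrap-around vertebral PTV with a spinal-cord
  dose trough, and a 2 cm lung sphere with a 1 cm PTV margin;
* planned dose — an analytic plateau x logistic-penumbra model per fraction
  that satisfies each case's coverage, max-dose window, conformity-index and
  OAR constraints on the film plane (the metrics module verifies them);
* delivery perturbations — seeded shift / rotation / dose-scaling / noise
  error modes with recorded ground truth, for parameter-recovery tests;
* a film forward model — dose -> net optical density per RGB channel with
  time-dependent darkening and scanner noise, invertible by the film
  dosimetry module.

All randomness derives from one integer seed per artifact through
``numpy.random.SeedSequence`` spawn keys, so identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cases import CaseDefinition, get_case
from .grid import MATERIALS, DosePlane, MaterialMask, StructureSet, circle_mask

__all__ = [
    "PhantomPlane",
    "PerturbationSpec",
    "FilmForwardModel",
    "FilmScan",
    "make_phantom_plane",
    "make_planned_dose",
    "perturb_dose",
    "render_film_scan",
    "isodose_radius",
    "child_rng",
    "GEOMETRY",
]

# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for (seed, counter...) tuples."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key)))


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

#: Film-plane geometry of the synthetic phantom, mm.  Representative of the
#: physical phantom, not a replica (the as-built drawings are not public).
GEOMETRY = {
    "soft_tissue": {
        "ptv_radius": 12.5,  # 2.5 cm diameter cylindrical PTV cross-section
        "plateau_radius": 15.0,
    },
    "spine": {
        "vertebra_radius": 16.0,
        "cortical_thickness": 2.0,
        "ptv_margin": 2.0,  # CTV (vertebral body) + 2 mm
        "cord_centre": (0.0, 8.0),  # posterior of body centre
        "cord_radius": 4.0,
        "canal_wall": 1.5,
        "prv_margin": 2.0,  # cord PRV = cord + 2 mm
        "esophagus_centre": (0.0, -27.0),
        "esophagus_radius": 5.0,
        "plateau_radius": 20.0,
        # logistic trough in distance-to-cord: floor, midpoint, width (mm)
        "trough_floor": 0.33,
        "trough_mid": 7.557,
        "trough_width": 1.3057,
    },
    "lung": {
        "target_radius": 10.0,  # 2 cm diameter sphere cross-section
        "ptv_margin": 10.0,  # 1 cm isotropic ITV->PTV margin
        "plateau_radius": 22.5,
    },
}

#: Plateau height as a fraction of the per-fraction prescription; inside the
#: 110-140% max-dose window required of every case and low enough that a
#: +10% delivery error stays inside the 0-20 Gy film calibration range.
PLATEAU_FRACTION = 1.20

#: Default 80-20% penumbra width of the logistic edge, mm.
PENUMBRA_80_20_MM = 3.0

#: Out-of-field scatter/leakage floor as a fraction of the per-fraction
#: prescription; real deliveries leave a low-dose bath outside the field.
OUT_OF_FIELD_FLOOR = 0.05

# 80-20 width of 1/(1+exp(r/s)) is 2*ln(4)*s
_PENUMBRA_SCALE = PENUMBRA_80_20_MM / (2.0 * math.log(4.0))


@dataclass
class PhantomPlane:
    """Material labels, structures and fiducials on one film plane."""

    case_id: str
    materials: MaterialMask
    structures: StructureSet
    fiducials: np.ndarray  # (n, 2) mm, n >= 3, non-collinear
    spacing: float
    origin: tuple[float, float]
    plane: str = "transverse"

    def __post_init__(self) -> None:
        self.fiducials = np.asarray(self.fiducials, dtype=float)
        if len(self.fiducials) < 3:
            raise ValueError("at least 3 fiducials required")
        centred = self.fiducials - self.fiducials.mean(axis=0)
        if np.linalg.svd(centred, compute_uv=False)[-1] < 1e-6:
            raise ValueError("fiducials must be non-collinear")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.materials.labels.shape


def _centred_origin(grid_shape: tuple[int, int], spacing: float) -> tuple[float, float]:
    ny, nx = grid_shape
    return (-spacing * (nx - 1) / 2.0, -spacing * (ny - 1) / 2.0)


def make_phantom_plane(
    case_id: str,
    grid_shape: tuple[int, int] = (200, 200),
    spacing: float = 0.5,
) -> PhantomPlane:
    """Build the synthetic phantom film plane for one audit case.

    The grid is pixel-centred with the origin at the plane centre.  Material
    labels follow :data:`sbrtaudit.grid.MATERIALS`; structures include the
    PTV and, for the spine, the cord, cord PRV and esophagus surrogate.
    """
    if not 0.1 <= spacing <= 2.0:
        raise ValueError("spacing must be within [0.1, 2.0] mm")
    case = get_case(case_id)  # raises on unknown id
    geo = GEOMETRY[case_id]
    origin = _centred_origin(grid_shape, spacing)
    labels = np.zeros(grid_shape, dtype=np.int32)  # plastic_water

    def disc(centre, radius):
        return circle_mask(grid_shape, spacing, origin, centre, radius)

    structures: dict[str, np.ndarray] = {}

    if case_id == "soft_tissue":
        structures["ptv"] = disc((0.0, 0.0), geo["ptv_radius"])
    elif case_id == "spine":
        body = disc((0.0, 0.0), geo["vertebra_radius"])
        trab = disc((0.0, 0.0), geo["vertebra_radius"] - geo["cortical_thickness"])
        cord = disc(geo["cord_centre"], geo["cord_radius"])
        canal = disc(geo["cord_centre"], geo["cord_radius"] + geo["canal_wall"])
        labels[body] = MATERIALS.index("cortical_bone")
        labels[trab] = MATERIALS.index("trabecular_bone")
        labels[canal & trab] = MATERIALS.index("cortical_bone")  # canal wall
        labels[cord] = MATERIALS.index("plastic_water")  # cord surrogate
        prv = disc(geo["cord_centre"], geo["cord_radius"] + geo["prv_margin"])
        ptv = disc((0.0, 0.0), geo["vertebra_radius"] + geo["ptv_margin"]) & ~prv
        structures.update(
            ptv=ptv,
            cord=cord,
            cord_prv=prv,
            esophagus=disc(geo["esophagus_centre"], geo["esophagus_radius"]),
        )
    elif case_id == "lung":
        labels[:] = MATERIALS.index("inhale_lung")
        target = disc((0.0, 0.0), geo["target_radius"])
        labels[target] = MATERIALS.index("lung_target")
        structures["ptv"] = disc((0.0, 0.0), geo["target_radius"] + geo["ptv_margin"])

    ny, nx = grid_shape
    half_x, half_y = spacing * (nx - 1) / 2.0, spacing * (ny - 1) / 2.0
    fx, fy = 0.8 * half_x, 0.8 * half_y  # pin cut-outs near the film corners
    fiducials = np.array([(-fx, -fy), (fx, -fy), (fx, fy), (-fx, fy)])

    return PhantomPlane(
        case_id=case_id,
        materials=MaterialMask(labels, spacing, origin),
        structures=StructureSet({k: v for k, v in structures.items()}, spacing, origin),
        fiducials=fiducials,
        spacing=spacing,
        origin=origin,
        plane=case.film_plane,
    )


# ---------------------------------------------------------------------------
# planned dose
# ---------------------------------------------------------------------------


def _edge_profile(r: np.ndarray, plateau_radius: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((r - plateau_radius) / _PENUMBRA_SCALE))


def _cord_trough(d: np.ndarray, geo: dict) -> np.ndarray:
    floor, mid, width = geo["trough_floor"], geo["trough_mid"], geo["trough_width"]
    return floor + (1.0 - floor) / (1.0 + np.exp(-(d - mid) / width))


def planned_dose_function(case_id: str):
    """Analytic per-fraction planned dose D(X, Y) in Gy for a case."""
    case = get_case(case_id)
    geo = GEOMETRY[case_id]
    plateau = PLATEAU_FRACTION * case.prescription_per_fraction

    floor = OUT_OF_FIELD_FLOOR * case.prescription_per_fraction

    def dose(X, Y):
        r = np.hypot(X, Y)
        f = _edge_profile(r, geo["plateau_radius"])
        d = plateau * f
        if case_id == "spine":
            cx, cy = geo["cord_centre"]
            d = d * _cord_trough(np.hypot(X - cx, Y - cy), geo)
        return d + floor * (1.0 - f)

    return dose


def isodose_radius(case_id: str, level_fraction: float) -> float:
    """Analytic radius (mm) of a prescription-relative isodose on the outer edge.

    Solves ``PLATEAU_FRACTION * f(r) + FLOOR * (1 - f(r)) = level_fraction``
    for the logistic edge profile; the spine cord trough is local and does
    not move the outer edge.
    """
    if not OUT_OF_FIELD_FLOOR < level_fraction < PLATEAU_FRACTION:
        raise ValueError("level must be between the scatter floor and the plateau")
    geo = GEOMETRY[case_id]
    return geo["plateau_radius"] + _PENUMBRA_SCALE * math.log(
        (PLATEAU_FRACTION - OUT_OF_FIELD_FLOOR) / (level_fraction - OUT_OF_FIELD_FLOOR) - 1.0
    )


def make_planned_dose(plane: PhantomPlane, case: CaseDefinition | None = None) -> DosePlane:
    """Per-fraction planned dose plane for a phantom film plane.

    The model is a circular plateau at ``PLATEAU_FRACTION`` of the
    per-fraction prescription with a logistic penumbra; the spine case
    multiplies in a logistic trough in distance to the cord so the cord PRV
    stays under its per-fraction limit while the wrap-around PTV keeps the
    required (>= 80%) coverage.
    """
    case = case or get_case(plane.case_id)
    if case.case_id != plane.case_id:
        raise ValueError("phantom plane and case definition disagree")
    shape = plane.grid_shape
    origin = plane.origin
    x = origin[0] + plane.spacing * np.arange(shape[1])
    y = origin[1] + plane.spacing * np.arange(shape[0])
    X, Y = np.meshgrid(x, y)
    values = planned_dose_function(case.case_id)(X, Y)
    return DosePlane(values=values, spacing=plane.spacing, origin=origin, plane=plane.plane)


# ---------------------------------------------------------------------------
# delivery perturbations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationSpec:
    """A known injected delivery error.

    shift/rotation are applied as a rigid motion of the delivered dose
    pattern; the scale factors are multiplicative (global, inside the PTV,
    outside the 50% isodose); ``noise_sigma`` is Gaussian dose noise as a
    fraction of the per-fraction prescription.  ``injected_mode`` records the
    intended failure-mode label for recovery tests.
    """

    shift: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    global_scale: float = 1.0
    infield_scale: float = 1.0
    outfield_scale: float = 1.0
    noise_sigma: float = 0.0
    injected_mode: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for s in (self.global_scale, self.infield_scale, self.outfield_scale):
            if s <= 0:
                raise ValueError("scale factors must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.shift == (0.0, 0.0)
            and self.rotation_deg == 0.0
            and self.global_scale == self.infield_scale == self.outfield_scale == 1.0
            and self.noise_sigma == 0.0
        )

    @classmethod
    def for_mode(cls, mode: str, seed: int = 0, **overrides) -> "PerturbationSpec":
        """Preset perturbations for the named failure modes."""
        rng = child_rng(seed, 901)
        theta = rng.uniform(0, 2 * np.pi)
        presets = {
            "IGRT mismatch": dict(shift=(3.0 * math.cos(theta), 3.0 * math.sin(theta))),
            "In-volume dose difference (low)": dict(infield_scale=0.90),
            "In-volume dose difference (high)": dict(infield_scale=1.10),
            "Other shift/misalignment": dict(rotation_deg=4.0, shift=(1.0 * math.cos(theta), 1.0 * math.sin(theta))),
            "Out of field dose (high)": dict(outfield_scale=2.5),
            "none": {},
        }
        if mode not in presets:
            raise KeyError(f"no perturbation preset for mode {mode!r}")
        kwargs = dict(presets[mode])
        kwargs.update(overrides)
        return cls(injected_mode=mode, seed=seed, **kwargs)


def perturb_dose(
    planned: DosePlane,
    spec: PerturbationSpec,
    structures: StructureSet | None = None,
    prescription_per_fraction: float | None = None,
) -> DosePlane:
    """Apply a known delivery perturbation to a planned dose plane.

    Rigid motion is implemented by bilinear resampling (same interpolation
    as the metrics module); the identity spec returns an exact copy.  The
    in-field scale needs the PTV structure, the out-of-field scale and the
    noise level need the per-fraction prescription.
    """
    vals = planned.values
    if not np.all(np.isfinite(vals)) or vals.min() < 0:
        raise ValueError("planned dose must be finite and non-negative")
    if spec.is_identity:
        return planned.copy()

    ny, nx = planned.shape
    fov = planned.spacing * min(nx, ny)
    if math.hypot(*spec.shift) > 0.25 * fov:
        raise ValueError("shift larger than 25% of the field of view")

    out = vals
    if spec.shift != (0.0, 0.0) or spec.rotation_deg != 0.0:
        X, Y = planned.meshgrid()
        cx = (planned.x[0] + planned.x[-1]) / 2.0
        cy = (planned.y[0] + planned.y[-1]) / 2.0
        th = math.radians(spec.rotation_deg)
        # delivered(x) = planned(T^-1 x): un-shift, then un-rotate about centre
        Xs, Ys = X - spec.shift[0] - cx, Y - spec.shift[1] - cy
        Xr = math.cos(th) * Xs + math.sin(th) * Ys + cx
        Yr = -math.sin(th) * Xs + math.cos(th) * Ys + cy
        out = planned.sample(Xr, Yr, fill_value=0.0)

    out = out * spec.global_scale
    if spec.infield_scale != 1.0:
        if structures is None or "ptv" not in structures:
            raise ValueError("in-field scaling requires the PTV structure")
        out = np.where(structures["ptv"], out * spec.infield_scale, out)
    if spec.outfield_scale != 1.0:
        if prescription_per_fraction is None:
            raise ValueError("out-of-field scaling requires the prescription")
        outfield = planned.values < 0.5 * prescription_per_fraction
        out = np.where(outfield, out * spec.outfield_scale, out)
    if spec.noise_sigma > 0:
        if prescription_per_fraction is None:
            raise ValueError("dose noise requires the prescription")
        rng = child_rng(spec.seed, 101)
        out = out + rng.normal(
            0.0, spec.noise_sigma * prescription_per_fraction, size=out.shape
        )
        out = np.clip(out, 0.0, None)
    return replace(planned, values=np.ascontiguousarray(out))


# ---------------------------------------------------------------------------
# film forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilmForwardModel:
    """Radiochromic-film response: dose -> net optical density per channel.

    ``netOD_ch(D, t) = a*D / (1 + b*D) * (1 + c*ln(t / t_ref))`` — a
    saturating rational response (zero at zero dose, strictly increasing on
    the 0–20 Gy calibration range) with a slow logarithmic post-irradiation
    darkening relative to the reference scan time ``t_ref``.  Channel order
    is (R, G, B); the red channel is the most sensitive.
    """

    a: tuple[float, float, float] = (0.0585, 0.0350, 0.0180)  # per Gy
    b: tuple[float, float, float] = (0.030, 0.020, 0.012)  # per Gy
    darkening: tuple[float, float, float] = (0.015, 0.015, 0.012)
    t_ref_hours: float = 24.0
    noise_sigma: float = 0.002  # scanner noise in netOD
    dose_range: tuple[float, float] = (0.0, 20.0)
    delay_range_hours: tuple[float, float] = (6.0, 120.0)

    def netod(self, dose: np.ndarray, channel: int, delay_hours: float | None = None) -> np.ndarray:
        delay = self.t_ref_hours if delay_hours is None else delay_hours
        base = self.a[channel] * dose / (1.0 + self.b[channel] * dose)
        return base * self.darkening_factor(channel, delay)

    def darkening_factor(self, channel: int, delay_hours: float) -> float:
        if delay_hours <= 0:
            raise ValueError("scan delay must be positive")
        return 1.0 + self.darkening[channel] * math.log(delay_hours / self.t_ref_hours)

    def dose_from_netod(self, netod: np.ndarray, channel: int) -> np.ndarray:
        """Analytic inverse of the rational response at the reference time."""
        a, b = self.a[channel], self.b[channel]
        return netod / (a - b * netod)


@dataclass
class FilmScan:
    """Three-channel netOD grids for one scanned film."""

    netod: np.ndarray  # (3, ny, nx)
    spacing: float
    origin: tuple[float, float]
    plane: str = "transverse"
    scan_delay_hours: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.netod = np.asarray(self.netod, dtype=float)
        if self.netod.ndim != 3 or self.netod.shape[0] != 3:
            raise ValueError("film scan must hold 3 channel grids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.netod.shape[1:]

    # 16-bit transmission value of unexposed film used for TIFF round trips
    _PV0 = 42000.0

    def to_tiff(self, path) -> None:
        """Write as a 48-bit RGB TIFF (16 bits/channel transmission values)."""
        import tifffile

        pv = np.clip(self._PV0 * 10.0 ** (-self.netod), 0, 65535)
        rgb = np.moveaxis(np.rint(pv).astype(np.uint16), 0, -1)
        tifffile.imwrite(
            str(path),
            rgb,
            photometric="rgb",
            resolution=(25.4 / self.spacing, 25.4 / self.spacing),
        )

    @classmethod
    def from_tiff(cls, path, spacing: float, origin=(0.0, 0.0), scan_delay_hours: float = 24.0) -> "FilmScan":
        import tifffile

        rgb = tifffile.imread(str(path)).astype(float)
        netod = -np.log10(np.clip(np.moveaxis(rgb, -1, 0), 1.0, None) / cls._PV0)
        return cls(netod=netod, spacing=spacing, origin=origin, scan_delay_hours=scan_delay_hours)


class DoseRangeError(ValueError):
    """Dose outside the film calibration range."""


def render_film_scan(
    dose: DosePlane,
    model: FilmForwardModel,
    scan_delay_hours: float | None = None,
    seed: int = 0,
) -> FilmScan:
    """Simulate scanning a film exposed to ``dose``.

    Applies the forward response and darkening for the scan delay, then adds
    seeded Gaussian scanner noise in netOD.  Doses beyond the calibration
    range are rejected.
    """
    delay = model.t_ref_hours if scan_delay_hours is None else scan_delay_hours
    vals = dose.values
    lo, hi = model.dose_range
    if np.nanmax(vals) > hi or np.nanmin(vals) < lo:
        raise DoseRangeError(
            f"dose outside the film calibration range [{lo}, {hi}] Gy"
        )
    rng = child_rng(seed, 201)
    channels = []
    for ch in range(3):
        grid = model.netod(vals, ch, delay)
        if model.noise_sigma > 0:
            grid = grid + rng.normal(0.0, model.noise_sigma, size=grid.shape)
        channels.append(grid)
    return FilmScan(
        netod=np.stack(channels),
        spacing=dose.spacing,
        origin=dose.origin,
        plane=dose.plane,
        scan_delay_hours=delay,
        seed=seed,
    )


#: Nominal 12-level calibration exposure set, Gy.
CALIBRATION_DOSES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0)


def make_calibration_dataset(
    model: FilmForwardModel,
    doses=CALIBRATION_DOSES,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Synthesize a calibration film set from the forward model.

    Exposes one film per dose level, reads netOD at the reference scan time
    and optionally adds Gaussian noise, relative to each level's netOD
    (``noise_sigma = 0.005`` means 0.5% netOD noise).  Returns a
    :class:`sbrtaudit.film.CalibrationDataset`.
    """
    from .film import CalibrationDataset

    doses = np.asarray(doses, dtype=float)
    netod = np.stack([model.netod(doses, ch) for ch in range(3)], axis=1)
    if noise_sigma > 0:
        rng = child_rng(seed, 301)
        netod = netod * (1.0 + rng.normal(0.0, noise_sigma, size=netod.shape))
    return CalibrationDataset(
        doses=doses, netod=netod, scan_time_hours=model.t_ref_hours
    )
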