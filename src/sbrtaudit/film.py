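"""Film calibration, darkening correction, dose conversion and check-film QC.

The audit films are calibrated offsite against an ionization chamber with a
12-level curve spanning 0–20 Gy.  Because the calibration scan and the audit
scan happen at different post-irradiation times, a dose-dependent darkening
correction refers every scan to the calibration reference time.  Two check
films irradiated on the audited machine to chamber-verified doses are
co-scanned with the audit films; a single through-origin linear scale factor
maps calibrated film dose onto chamber dose, with a 5% quality-control limit
— conversion is refused ("rescan required") beyond it.

Calibration functional forms are pluggable (see :data:`CALIBRATION_FORMS`);
the default is the rational saturating response shared with the synthetic
film forward model, which has an analytic monotone inverse.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .grid import DosePlane

__all__ = [
    "CalibrationDataset",
    "CalibrationModel",
    "CheckFilmPair",
    "ScalingQC",
    "CalibrationQualityError",
    "RescanRequiredError",
    "fit_calibration",
    "apply_darkening_correction",
    "scan_to_dose",
    "check_film_qc",
]

CHANNELS = ("R", "G", "B")


class CalibrationQualityError(ValueError):
    """Calibration data are non-monotone or fit residuals exceed 3%."""


class RescanRequiredError(RuntimeError):
    """Check-film scaling outside the QC limit; the scan must be repeated."""


# ---------------------------------------------------------------------------
# pluggable calibration forms: netOD(D; params) and its inverse dose(netOD)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationForm:
    name: str
    n_params: int
    netod: Callable  # netod(dose, *params)
    dose: Callable  # dose(netod, *params)
    p0: tuple[float, ...]
    fit_domain: str = "netod"  # which direction the least squares runs in
    bounds: tuple = (-np.inf, np.inf)


def _rational_netod(dose, a, b):
    return a * dose / (1.0 + b * dose)


def _rational_dose(netod, a, b):
    return netod / (a - b * netod)


def _power_netod(dose, p1, p2, p3):
    # inverse of dose = p1*netOD + p2*netOD**p3, evaluated numerically
    dose = np.asarray(dose, dtype=float)
    out = np.zeros_like(dose)
    grid = np.linspace(0.0, 1.5, 4096)
    dgrid = _power_dose(grid, p1, p2, p3)
    return np.interp(dose, dgrid, grid)


def _power_dose(netod, p1, p2, p3):
    netod = np.asarray(netod, dtype=float)
    return p1 * netod + p2 * np.sign(netod) * np.abs(netod) ** p3


CALIBRATION_FORMS: dict[str, CalibrationForm] = {
    "rational": CalibrationForm("rational", 2, _rational_netod, _rational_dose, (0.05, 0.02)),
    "power": CalibrationForm(
        "power", 3, _power_netod, _power_dose, (15.0, 20.0, 2.5),
        fit_domain="dose", bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 10.0]),
    ),
}


# ---------------------------------------------------------------------------
# datasets and models
# ---------------------------------------------------------------------------


@dataclass
class CalibrationDataset:
    """Delivered doses and measured per-channel netOD for the curve films."""

    doses: np.ndarray  # (n,) Gy, strictly increasing, first level 0
    netod: np.ndarray  # (n, 3)
    beam: str = "10x10 cm2 6 MV"
    scan_time_hours: float = 24.0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.netod = np.asarray(self.netod, dtype=float)
        if len(self.doses) < 5:
            raise ValueError("calibration needs at least 5 dose levels")
        if not np.all(np.diff(self.doses) > 0):
            raise ValueError("calibration doses must be strictly increasing")
        if self.doses[0] != 0.0:
            raise ValueError("calibration must include a zero-dose level")
        if self.netod.shape != (len(self.doses), 3):
            raise ValueError("netod must be (n_levels, 3)")

    @classmethod
    def from_csv(cls, path) -> "CalibrationDataset":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            doses=df["dose_Gy"].to_numpy(),
            netod=df[["netOD_R", "netOD_G", "netOD_B"]].to_numpy(),
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "dose_Gy": self.doses,
                "netOD_R": self.netod[:, 0],
                "netOD_G": self.netod[:, 1],
                "netOD_B": self.netod[:, 2],
            }
        ).to_csv(path, index=False)


@dataclass
class CalibrationModel:
    """Fitted per-channel dose <-> netOD response with darkening parameters."""

    form: str
    params: np.ndarray  # (3, n_params)
    darkening: tuple[float, float, float] = (0.015, 0.015, 0.012)
    t_ref_hours: float = 24.0
    delay_range_hours: tuple[float, float] = (6.0, 120.0)
    dose_range: tuple[float, float] = (0.0, 20.0)
    max_relative_residual: float = 0.0
    netod_noise_sigma: float = 0.002

    def netod(self, dose, channel: int):
        f = CALIBRATION_FORMS[self.form]
        return f.netod(np.asarray(dose, dtype=float), *self.params[channel])

    def dose(self, netod, channel: int):
        f = CALIBRATION_FORMS[self.form]
        return f.dose(np.asarray(netod, dtype=float), *self.params[channel])

    def sensitivity(self, dose, channel: int, eps: float = 1e-4):
        """d netOD / d dose, used for inverse-variance channel weighting."""
        d = np.asarray(dose, dtype=float)
        return (self.netod(d + eps, channel) - self.netod(np.clip(d - eps, 0, None), channel)) / (
            d + eps - np.clip(d - eps, 0, None)
        )

    def max_netod(self, channel: int) -> float:
        return float(self.netod(self.dose_range[1], channel))

    def to_json(self, path) -> None:
        payload = {
            "form": self.form,
            "params": self.params.tolist(),
            "darkening": list(self.darkening),
            "t_ref_hours": self.t_ref_hours,
            "delay_range_hours": list(self.delay_range_hours),
            "dose_range": list(self.dose_range),
            "max_relative_residual": self.max_relative_residual,
            "netod_noise_sigma": self.netod_noise_sigma,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            form=payload["form"],
            params=np.asarray(payload["params"], dtype=float),
            darkening=tuple(payload["darkening"]),
            t_ref_hours=payload["t_ref_hours"],
            delay_range_hours=tuple(payload["delay_range_hours"]),
            dose_range=tuple(payload["dose_range"]),
            max_relative_residual=payload["max_relative_residual"],
            netod_noise_sigma=payload.get("netod_noise_sigma", 0.002),
        )


def fit_calibration(
    data: CalibrationDataset,
    form: str = "rational",
    darkening: tuple[float, float, float] = (0.015, 0.015, 0.012),
    residual_limit: float = 0.03,
) -> CalibrationModel:
    """Least-squares per-channel fit of the dose-response curve.

    Verifies monotonicity of each fitted channel on a dense dose grid and
    reports the maximum relative dose residual over the non-zero levels;
    residuals beyond ``residual_limit`` raise :class:`CalibrationQualityError`.
    """
    spec = CALIBRATION_FORMS[form]
    for ch in range(3):
        if not np.all(np.diff(data.netod[:, ch]) > 0):
            raise CalibrationQualityError(
                f"channel {CHANNELS[ch]}: netOD not monotone in dose"
            )
    params = np.empty((3, spec.n_params))
    for ch in range(3):
        # seed the fit from the observed low-dose slope where possible
        p0 = list(spec.p0)
        if form == "rational":
            p0[0] = data.netod[1, ch] / max(data.doses[1], 1e-9)
        elif form == "power":
            p0[0] = data.doses[1] / max(data.netod[1, ch], 1e-9)
        if spec.fit_domain == "netod":
            popt, _ = curve_fit(
                spec.netod, data.doses, data.netod[:, ch], p0=p0,
                bounds=spec.bounds, maxfev=20000,
            )
        else:
            popt, _ = curve_fit(
                spec.dose, data.netod[:, ch], data.doses, p0=p0,
                bounds=spec.bounds, maxfev=20000,
            )
        params[ch] = popt

    model = CalibrationModel(
        form=form,
        params=params,
        darkening=darkening,
        t_ref_hours=data.scan_time_hours,
        dose_range=(float(data.doses[0]), float(data.doses[-1])),
    )
    dense = np.linspace(model.dose_range[0], model.dose_range[1], 512)
    for ch in range(3):
        if not np.all(np.diff(model.netod(dense, ch)) > 0):
            raise CalibrationQualityError(
                f"channel {CHANNELS[ch]}: fitted response not monotone"
            )
    nz = data.doses > 0
    worst = 0.0
    for ch in range(3):
        pred = model.dose(data.netod[nz, ch], ch)
        worst = max(worst, float(np.max(np.abs(pred - data.doses[nz]) / data.doses[nz])))
    model.max_relative_residual = worst
    if worst > residual_limit:
        raise CalibrationQualityError(
            f"max relative dose residual {worst:.2%} exceeds {residual_limit:.0%}"
        )
    # zero-dose anchor: every supported form passes through the origin
    assert abs(float(model.dose(0.0, 0))) < 1e-12
    return model


# ---------------------------------------------------------------------------
# darkening correction
# ---------------------------------------------------------------------------


def apply_darkening_correction(
    netod: np.ndarray, scan_delay_hours: float, model: CalibrationModel
) -> np.ndarray:
    """Refer a (3, ny, nx) netOD stack to the calibration reference time.

    The correction divides out ``1 + c_ch * ln(t / t_ref)``; it is the exact
    identity at ``t = t_ref``.  Delays outside the validated range are
    corrected anyway but flagged with a warning.
    """
    if scan_delay_hours <= 0:
        raise ValueError("scan delay must be positive")
    lo, hi = model.delay_range_hours
    if not lo <= scan_delay_hours <= hi:
        import warnings

        warnings.warn(
            f"scan delay {scan_delay_hours} h outside validated range [{lo}, {hi}] h",
            stacklevel=2,
        )
    if scan_delay_hours == model.t_ref_hours:
        return np.asarray(netod, dtype=float).copy()
    out = np.empty_like(np.asarray(netod, dtype=float))
    for ch in range(3):
        factor = 1.0 + model.darkening[ch] * math.log(scan_delay_hours / model.t_ref_hours)
        out[ch] = netod[ch] / factor
    return out


# ---------------------------------------------------------------------------
# check-film QC
# ---------------------------------------------------------------------------


@dataclass
class CheckFilmPair:
    """Chamber dose and calibrated film dose for the two session check films."""

    chamber_doses: tuple[float, float]  # Gy, e.g. (10, 15) or (5, 15)
    film_doses: tuple[float, float]  # Gy from the calibration curve
    scan_id: str = ""

    def __post_init__(self) -> None:
        if min(self.chamber_doses) <= 0 or min(self.film_doses) <= 0:
            raise ValueError("check-film doses must be positive")


@dataclass
class ScalingQC:
    """Through-origin linear scaling of the session, with its 5% limit."""

    scale_factor: float
    control_limit: float = 0.05
    residual: float = 0.0

    @property
    def within_limit(self) -> bool:
        # the limit names the boundary of acceptability: 5% exactly passes
        return abs(self.scale_factor - 1.0) <= self.control_limit + 1e-12


def check_film_qc(
    pair: CheckFilmPair, limit: float = 0.05, residual_limit: float = 0.02
) -> ScalingQC:
    """Fit the session scale factor from the check films.

    The factor is the least-squares through-origin slope mapping calibrated
    film doses onto chamber doses; the residual is the worst remaining
    relative mismatch.  A residual beyond ``residual_limit`` indicates a
    non-linear inconsistency between the two check films.
    """
    f = np.asarray(pair.film_doses, dtype=float)
    c = np.asarray(pair.chamber_doses, dtype=float)
    k = float(np.dot(f, c) / np.dot(f, f))
    residual = float(np.max(np.abs(c - k * f) / c))
    if residual > residual_limit:
        raise CalibrationQualityError(
            f"check films mutually inconsistent (residual {residual:.2%})"
        )
    return ScalingQC(scale_factor=k, control_limit=limit, residual=residual)


# ---------------------------------------------------------------------------
# scan -> dose
# ---------------------------------------------------------------------------


def scan_to_dose(scan, model: CalibrationModel, qc: ScalingQC) -> DosePlane:
    """Convert a film scan to an absolute dose plane.

    Applies the darkening correction for the scan delay, inverts each
    channel's calibration, combines channels by inverse-variance weighting
    (sensitivity-propagated scanner noise), and multiplies by the session
    scale factor.  Pixels outside the calibrated netOD range are masked NaN.
    Refuses to convert when the check-film QC failed.
    """
    if not qc.within_limit:
        raise RescanRequiredError(
            f"rescan required: check-film scaling {qc.scale_factor:.4f} "
            f"outside the {qc.control_limit:.0%} limit"
        )
    corrected = apply_darkening_correction(scan.netod, scan.scan_delay_hours, model)
    doses = np.empty_like(corrected)
    weights = np.empty_like(corrected)
    for ch in range(3):
        od = corrected[ch]
        valid = (od >= -5 * model.netod_noise_sigma) & (od <= model.max_netod(ch))
        od_cl = np.clip(od, 0.0, model.max_netod(ch))
        d = model.dose(od_cl, ch)
        d[~valid] = np.nan
        doses[ch] = d
        sens = model.sensitivity(np.nan_to_num(d), ch)
        var = (model.netod_noise_sigma / np.clip(sens, 1e-9, None)) ** 2
        weights[ch] = 1.0 / var
    weights = np.where(np.isfinite(doses), weights, 0.0)
    wsum = weights.sum(axis=0)
    combined = np.where(
        wsum > 0,
        np.nansum(doses * weights, axis=0) / np.where(wsum > 0, wsum, 1.0),
        np.nan,
    )
    return DosePlane(
        values=qc.scale_factor * combined,
        spacing=scan.spacing,
        origin=scan.origin,
        plane=scan.plane,
    )
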