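"""Film-to-plan rigid registration from fiducial cut-out landmarks.

The scanned audit film is localized in the treatment frame of reference by
matching physical pin cut-outs on the film to their known positions on the
planning CT.  Alignment is a 2D rigid (rotation + translation) least-squares
fit — the orthogonal Procrustes solution — performed independently by two
observers; the two transforms must agree to better than 0.5 mm over the film
corners, the worst-case points for a rotation discrepancy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import DosePlane

__all__ = [
    "LandmarkSet",
    "RigidTransform2D",
    "fit_rigid",
    "observer_agreement",
    "resample_to_plan",
]

OBSERVER_TOLERANCE_MM = 0.5


@dataclass
class LandmarkSet:
    """Paired film-plane / plan-grid landmark positions in mm."""

    film: np.ndarray  # (n, 2)
    plan: np.ndarray  # (n, 2)
    observer: str = "observer1"

    def __post_init__(self) -> None:
        self.film = np.asarray(self.film, dtype=float)
        self.plan = np.asarray(self.plan, dtype=float)
        if self.film.shape != self.plan.shape or self.film.ndim != 2 or self.film.shape[1] != 2:
            raise ValueError("landmarks must be matched (n, 2) arrays")
        if len(self.film) < 3:
            raise ValueError("at least 3 landmark pairs required")
        centred = self.film - self.film.mean(axis=0)
        if np.linalg.svd(centred, compute_uv=False)[-1] < 1e-9:
            raise ValueError("film landmarks are collinear")

    @classmethod
    def from_csv(cls, path, observer: str | None = None) -> "LandmarkSet":
        import pandas as pd

        df = pd.read_csv(path)
        if observer is not None:
            df = df[df["observer"] == observer]
        obs = df["observer"].iloc[0] if "observer" in df else "observer1"
        return cls(
            film=df[["film_x_mm", "film_y_mm"]].to_numpy(),
            plan=df[["plan_x_mm", "plan_y_mm"]].to_numpy(),
            observer=str(obs),
        )


@dataclass
class RigidTransform2D:
    """Pure rotation + translation mapping film coordinates to plan coordinates."""

    rotation_deg: float
    translation: tuple[float, float]
    rms_residual_mm: float = 0.0

    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        return np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix().T + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform2D":
        r = self.matrix()
        t = -r.T @ np.asarray(self.translation)
        return RigidTransform2D(-self.rotation_deg, (float(t[0]), float(t[1])), self.rms_residual_mm)

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """self o first (apply ``first``, then ``self``)."""
        r = self.matrix()
        t = r @ np.asarray(first.translation) + np.asarray(self.translation)
        return RigidTransform2D(
            self.rotation_deg + first.rotation_deg, (float(t[0]), float(t[1]))
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rotation_deg": self.rotation_deg,
                    "translation_mm": list(self.translation),
                    "rms_residual_mm": self.rms_residual_mm,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "RigidTransform2D":
        d = json.loads(Path(path).read_text())
        return cls(d["rotation_deg"], tuple(d["translation_mm"]), d["rms_residual_mm"])

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, (0.0, 0.0))


def fit_rigid(landmarks: LandmarkSet, residual_warn_mm: float = 1.0) -> RigidTransform2D:
    """Least-squares rigid transform (2D orthogonal Procrustes, no scaling).

    Invariant to landmark ordering.  An RMS residual above 1 mm flags suspect
    landmark entry with a warning.
    """
    a = landmarks.film
    b = landmarks.plan
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    t = cb - r @ ca
    rot = math.degrees(math.atan2(r[1, 0], r[0, 0]))
    fitted = a @ r.T + t
    rms = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    if rms > residual_warn_mm:
        import warnings

        warnings.warn(
            f"registration RMS residual {rms:.2f} mm > {residual_warn_mm} mm: "
            "suspect landmark entry",
            stacklevel=2,
        )
    return RigidTransform2D(rot, (float(t[0]), float(t[1])), rms)


def observer_agreement(
    t1: RigidTransform2D,
    t2: RigidTransform2D,
    extent_mm: tuple[float, float],
    tolerance_mm: float = OBSERVER_TOLERANCE_MM,
) -> tuple[float, bool]:
    """Worst-case discrepancy of two alignments over the film corners.

    ``extent_mm`` is the film half-extent (hx, hy); the discrepancy is the
    maximum over the four corners of ``|t1(p) - t2(p)|`` and the observers
    agree iff it is strictly below the tolerance (default 0.5 mm).
    """
    hx, hy = extent_mm
    corners = np.array([(-hx, -hy), (hx, -hy), (hx, hy), (-hx, hy)])
    delta = t1.apply(corners) - t2.apply(corners)
    worst = float(np.max(np.hypot(delta[:, 0], delta[:, 1])))
    return worst, worst < tolerance_mm


def resample_to_plan(
    measured: DosePlane,
    transform: RigidTransform2D,
    plan_grid: DosePlane,
    min_overlap: float = 0.5,
) -> DosePlane:
    """Resample the measured film dose onto the plan grid.

    ``transform`` maps film coordinates into plan coordinates; each plan
    pixel centre is pulled back through its inverse and sampled bilinearly
    from the film.  Pixels outside the film are NaN; less than
    ``min_overlap`` valid coverage of the plan grid is an error.
    """
    X, Y = plan_grid.meshgrid()
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    film_pts = transform.inverse().apply(pts)
    vals = measured.sample(film_pts[:, 0], film_pts[:, 1]).reshape(plan_grid.shape)
    overlap = float(np.mean(np.isfinite(vals)))
    if overlap < min_overlap:
        raise ValueError(
            f"film covers only {overlap:.0%} of the plan grid after alignment"
        )
    return DosePlane(
        values=vals,
        spacing=plan_grid.spacing,
        origin=plan_grid.origin,
        plane=plan_grid.plane,
    )
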