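"""2D dose planes, material masks and their on-disk formats.

The :class:`DosePlane` is the currency every stage of the audit pipeline
trades in: a rectangular grid of absorbed dose (Gy) on the film plane with
isotropic pixel spacing and a physical origin, both in millimetres.  Pixels
are addressed ``values[iy, ix]`` with ``x`` running along columns (left-right
on the film) and ``y`` along rows (anterior-posterior on a transverse film).
Invalid pixels (outside the scanned film, outside the calibrated dose range)
are NaN.

Planes are persisted as a small self-describing plain-text format and can
also be extracted from a single-frame DICOM RT Dose object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DosePlane",
    "MaterialMask",
    "StructureSet",
    "MATERIALS",
    "read_grid",
    "write_grid",
]

#: Phantom materials on the film plane, in label order.
MATERIALS = (
    "plastic_water",
    "cortical_bone",
    "trabecular_bone",
    "inhale_lung",
    "lung_target",
)


@dataclass
class DosePlane:
    """A 2D dose grid in Gy with spacing/origin metadata.

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Dose in Gy; NaN marks invalid pixels.
    spacing : float
        Isotropic pixel pitch in mm.
    origin : (float, float)
        ``(x0, y0)`` position in mm of the centre of pixel ``[0, 0]``.
    plane : str
        Anatomical film plane, ``"transverse"`` or ``"coronal"``.
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    plane: str = "transverse"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("dose plane must be 2D")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x(self) -> np.ndarray:
        """Pixel-centre x coordinates (mm), length nx."""
        return self.origin[0] + self.spacing * np.arange(self.shape[1])

    @property
    def y(self) -> np.ndarray:
        """Pixel-centre y coordinates (mm), length ny."""
        return self.origin[1] + self.spacing * np.arange(self.shape[0])

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of pixel centres in mm."""
        return (self.x[0], self.x[-1], self.y[0], self.y[-1])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (X, Y) coordinate arrays matching ``values``."""
        return np.meshgrid(self.x, self.y)

    def same_grid(self, other: "DosePlane", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )

    # -- sampling -----------------------------------------------------------
    def interpolator(self, fill_value: float = np.nan) -> RegularGridInterpolator:
        """Bilinear interpolator over (y, x) mm coordinates."""
        return RegularGridInterpolator(
            (self.y, self.x),
            self.values,
            method="linear",
            bounds_error=False,
            fill_value=fill_value,
        )

    def sample(self, x, y, fill_value: float = np.nan) -> np.ndarray:
        """Bilinear dose at physical positions (mm); NaN outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shape = np.broadcast_shapes(x.shape, y.shape)
        pts = np.stack([np.broadcast_to(y, shape).ravel(),
                        np.broadcast_to(x, shape).ravel()], axis=-1)
        return self.interpolator(fill_value=fill_value)(pts).reshape(shape)

    def copy(self) -> "DosePlane":
        return replace(self, values=self.values.copy())

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class MaterialMask:
    """Per-pixel material labels congruent with a :class:`DosePlane`.

    ``labels`` holds integer indices into ``names`` (default: the phantom
    material set :data:`MATERIALS`).
    """

    labels: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    names: tuple[str, ...] = MATERIALS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("material mask must be 2D")
        if self.labels.min() < 0 or self.labels.max() >= len(self.names):
            raise ValueError("mask labels outside the enumerated material set")

    def region(self, name: str) -> np.ndarray:
        """Boolean mask of pixels with the given material."""
        return self.labels == self.names.index(name)

    def present(self) -> list[str]:
        return [self.names[i] for i in np.unique(self.labels)]


@dataclass
class StructureSet:
    """Named boolean anatomical regions (PTV, cord PRV, ...) on one grid."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    spacing: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return sorted(self.masks)


# ---------------------------------------------------------------------------
# plain-text grid format
# ---------------------------------------------------------------------------

_GRID_MAGIC = "# dose-grid v1"


def write_grid(plane: DosePlane, path: str | Path, units: str = "Gy") -> None:
    """Write a plane in the plain-text grid format.

    Header lines carry nx, ny, spacing and origin in mm, units and the
    anatomical plane; the body is ny rows of nx values (row major).
    """
    path = Path(path)
    ny, nx = plane.shape
    with path.open("w") as fh:
        fh.write(f"{_GRID_MAGIC}\n")
        fh.write(f"nx {nx}\n")
        fh.write(f"ny {ny}\n")
        fh.write(f"spacing_mm {plane.spacing!r}\n")
        fh.write(f"origin_mm {plane.origin[0]!r} {plane.origin[1]!r}\n")
        fh.write(f"units {units}\n")
        fh.write(f"plane {plane.plane}\n")
        np.savetxt(fh, plane.values, fmt="%.8g")


def read_grid(path: str | Path) -> DosePlane:
    """Read a plane written by :func:`write_grid`."""
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        first = fh.readline().strip()
        if first != _GRID_MAGIC:
            raise ValueError(f"{path}: not a dose-grid file")
        for _ in range(6):
            key, _, val = fh.readline().strip().partition(" ")
            header[key] = val
        values = np.loadtxt(fh)
    nx, ny = int(header["nx"]), int(header["ny"])
    values = values.reshape(ny, nx)
    ox, oy = (float(v) for v in header["origin_mm"].split())
    return DosePlane(
        values=values,
        spacing=float(header["spacing_mm"]),
        origin=(ox, oy),
        plane=header.get("plane", "transverse"),
    )


def write_mask(mask: MaterialMask, path: str | Path) -> None:
    """Write a labelled mask as a grid file plus a sidecar label JSON."""
    path = Path(path)
    plane = DosePlane(mask.labels.astype(float), mask.spacing, mask.origin)
    write_grid(plane, path, units="label")
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    sidecar.write_text(json.dumps({str(i): n for i, n in enumerate(mask.names)}))


def read_mask(path: str | Path) -> MaterialMask:
    path = Path(path)
    plane = read_grid(path)
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        table: Mapping[str, str] = json.loads(sidecar.read_text())
        names = tuple(table[str(i)] for i in range(len(table)))
    else:
        names = MATERIALS
    return MaterialMask(
        labels=np.rint(plane.values).astype(np.int32),
        spacing=plane.spacing,
        origin=plane.origin,
        names=names,
    )


def plane_from_dicom(path: str | Path, frame: int = 0) -> DosePlane:
    """Extract a single frame of a DICOM RT Dose object as a plane.

    The frame is scaled by DoseGridScaling; pixel spacing and the image
    position patient (x, y) become the plane metadata.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 3:
        arr = arr[frame]
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = arr.astype(float) * scaling
    spacing = float(ds.PixelSpacing[0])
    if abs(float(ds.PixelSpacing[0]) - float(ds.PixelSpacing[1])) > 1e-6:
        raise ValueError("anisotropic RT Dose grids are not supported")
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    return DosePlane(values=values, spacing=spacing, origin=(float(ipp[0]), float(ipp[1])))


def circle_mask(shape: tuple[int, int], spacing: float, origin: tuple[float, float],
                centre: tuple[float, float], radius_mm: float) -> np.ndarray:
    """Boolean disc of the given physical radius (pixel-centre inclusion)."""
    ny, nx = shape
    x = origin[0] + spacing * np.arange(nx)
    y = origin[1] + spacing * np.arange(ny)
    X, Y = np.meshgrid(x, y)
    return (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 <= radius_mm**2
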