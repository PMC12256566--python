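"""Medium-dependent dose corrections for film and point-detector readings.

Film and diamond-detector readings made inside bone or lung equivalent
materials must be converted into the dose quantity the planning algorithm
reports — dose-to-medium in medium (Dm,m) or dose-to-water in water (Dw,w).
The conversion is a per-material multiplicative factor ``k_med``, applied
pixel-wise on the film plane using the phantom material mask and as a scalar
to point readings.  A water-to-tissue factor (default 0.992) applies to
plastic-water film regions of the soft-tissue and spine cases.

The numeric ``k_med`` values are measurement-campaign specific and must be
supplied by the user for real data; the shipped defaults are unity apart
from the water-to-tissue factor, so the table structure is exercised while
no unvalidated physics is injected.  ``Dw,m`` reporting is not supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import DosePlane, MaterialMask

__all__ = [
    "KmedTable",
    "PointCorrectionSet",
    "apply_kmed_map",
    "correct_point_reading",
    "WATER_TO_TISSUE",
    "REPORTING_MODES",
]

WATER_TO_TISSUE = 0.992
REPORTING_MODES = ("Dmm", "Dww")

#: Cases whose plastic-water film regions receive the water-to-tissue factor.
WATER_TO_TISSUE_CASES = ("soft_tissue", "spine")


@dataclass
class KmedTable:
    """(material, reporting mode) -> multiplicative correction factor.

    ``factors`` maps material name to ``{"Dmm": f, "Dww": f}``; every entry
    carries an optional provenance note.  Factors outside [0.8, 1.2] are
    rejected as physically implausible for these materials.
    """

    factors: dict[str, dict[str, float]]
    water_to_tissue: float = WATER_TO_TISSUE
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for material, modes in self.factors.items():
            for mode, f in modes.items():
                if mode not in REPORTING_MODES:
                    raise ValueError(f"unsupported reporting mode {mode!r}")
                if not 0.8 <= f <= 1.2:
                    raise ValueError(
                        f"k_med {f} for {material}/{mode} outside [0.8, 1.2]"
                    )
        if not 0.8 <= self.water_to_tissue <= 1.2:
            raise ValueError("water-to-tissue factor outside [0.8, 1.2]")

    def factor(self, material: str, mode: str) -> float:
        try:
            return self.factors[material][mode]
        except KeyError:
            raise KeyError(
                f"k_med table has no entry for material {material!r} in mode {mode!r}"
            ) from None

    @classmethod
    def default(cls) -> "KmedTable":
        """Unit placeholder factors; supply a measured table for real use."""
        factors = {
            m: {"Dmm": 1.0, "Dww": 1.0}
            for m in ("plastic_water", "cortical_bone", "trabecular_bone", "inhale_lung", "lung_target")
        }
        return cls(
            factors=factors,
            provenance={m: "placeholder unity factor" for m in factors},
        )

    @classmethod
    def from_file(cls, path) -> "KmedTable":
        """Load from YAML or JSON keyed by material then reporting mode."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(
            factors={m: dict(v) for m, v in payload["factors"].items()},
            water_to_tissue=float(payload.get("water_to_tissue", WATER_TO_TISSUE)),
            provenance=dict(payload.get("provenance", {})),
        )

    def to_file(self, path) -> None:
        path = Path(path)
        payload = {
            "factors": self.factors,
            "water_to_tissue": self.water_to_tissue,
            "provenance": self.provenance,
        }
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(payload))
        else:
            path.write_text(json.dumps(payload, indent=2))


def apply_kmed_map(
    dose: DosePlane,
    mask: MaterialMask,
    table: KmedTable,
    mode: str,
    case_id: str | None = None,
) -> DosePlane:
    """Apply spatially-dependent medium corrections to a film dose plane.

    Each pixel is multiplied by the factor for its material label under the
    requested reporting mode.  When ``case_id`` names a soft-tissue or spine
    case, plastic-water pixels additionally receive the water-to-tissue
    factor (the lung case's plastic regions do not).  Pixels whose combined
    factor is exactly 1 are returned bit-identical.
    """
    if mode not in REPORTING_MODES:
        raise ValueError(f"unsupported reporting mode {mode!r} (Dw,m is not supported)")
    if mask.labels.shape != dose.shape:
        raise ValueError("material mask not congruent with the dose grid")
    factor = np.ones(dose.shape)
    for material in mask.present():
        f = table.factor(material, mode)
        if material == "plastic_water" and case_id in WATER_TO_TISSUE_CASES:
            f = f * table.water_to_tissue
        if f != 1.0:
            factor[mask.region(material)] = f
    values = np.where(factor != 1.0, dose.values * factor, dose.values)
    return DosePlane(values=values, spacing=dose.spacing, origin=dose.origin, plane=dose.plane)


@dataclass(frozen=True)
class PointCorrectionSet:
    """Scalar corrections for a diamond-detector point reading."""

    cross_calibration: float = 1.0
    orientation: float = 1.0
    kmed: float = 1.0

    @property
    def combined(self) -> float:
        return self.cross_calibration * self.orientation * self.kmed


def correct_point_reading(raw_reading: float, corrections: PointCorrectionSet) -> float:
    """Corrected point dose in Gy: reading times the combined factor."""
    if raw_reading <= 0:
        raise ValueError("point reading must be positive")
    return raw_reading * corrections.combined
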