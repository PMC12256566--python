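"""Audit case definitions: prescriptions, constraints and scoring context.

The audit comprises three SBRT cases measured on the anthropomorphic thorax
phantom:

* ``soft_tissue`` — a simple 2.5 cm cylindrical PTV in homogeneous
  water-equivalent plastic, 45 Gy in 3 fractions, coverage >= 95%.
* ``spine`` — a wrap-around vertebral PTV excluding the spinal-cord PRV with
  an anterior esophagus surrogate, 24 Gy in 2 fractions, coverage >= 80%
  (ideally >= 90%), cord PRV max 14 Gy / esophagus 18 Gy at 0.03 cc.
* ``lung`` — a 2 cm spherical target in inhale-lung material with a 1 cm
  isotropic PTV margin, 48 Gy in 4 fractions, coverage >= 98%.

All cases require the maximum dose within 110–140% of prescription and
conformity indices CI100 <= 1.2 and CI50 <= 5.0.  Doses on the film plane are
per fraction (the audit measures a single delivery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CaseDefinition", "get_case", "CASE_IDS"]

CASE_IDS = ("soft_tissue", "spine", "lung")


@dataclass(frozen=True)
class OarLimit:
    structure: str
    volume_cc: float
    max_gy: float  # over the full course


@dataclass(frozen=True)
class CaseDefinition:
    """Prescription, fractionation and constraint set for one audit case."""

    case_id: str
    prescription_total: float  # Gy over all fractions
    n_fractions: int
    coverage_requirement: float  # fraction of PTV at prescription isodose
    max_dose_window: tuple[float, float]  # fractions of prescription
    ci100_limit: float = 1.2
    ci50_limit: float = 5.0
    oar_limits: tuple[OarLimit, ...] = ()
    film_plane: str = "transverse"
    film_offset_mm: float = 0.0
    reporting_mode: str = "Dmm"

    def __post_init__(self) -> None:
        if self.prescription_total <= 0:
            raise ValueError("prescription must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if not 0 < self.coverage_requirement <= 1:
            raise ValueError("coverage requirement must be in (0, 1]")
        lo, hi = self.max_dose_window
        if not lo < hi:
            raise ValueError("max-dose window must have low < high")

    @property
    def prescription_per_fraction(self) -> float:
        return self.prescription_total / self.n_fractions


_CASES = {
    "soft_tissue": CaseDefinition(
        case_id="soft_tissue",
        prescription_total=45.0,
        n_fractions=3,
        coverage_requirement=0.95,
        max_dose_window=(1.10, 1.40),
    ),
    "spine": CaseDefinition(
        case_id="spine",
        prescription_total=24.0,
        n_fractions=2,
        coverage_requirement=0.80,
        max_dose_window=(1.10, 1.40),
        oar_limits=(
            OarLimit("cord_prv", 0.03, 14.0),
            OarLimit("esophagus", 0.03, 18.0),
        ),
    ),
    "lung": CaseDefinition(
        case_id="lung",
        prescription_total=48.0,
        n_fractions=4,
        coverage_requirement=0.98,
        max_dose_window=(1.10, 1.40),
        film_plane="coronal",
        film_offset_mm=3.0,
    ),
}


def get_case(case_id: str) -> CaseDefinition:
    """Look up one of the three audit cases by id."""
    try:
        return _CASES[case_id]
    except KeyError:
        raise KeyError(
            f"unknown case id {case_id!r}; expected one of {CASE_IDS}"
        ) from None
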