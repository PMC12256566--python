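"""Audit outcome classification, failure-mode tagging and cohort reporting.

Each measured plan is scored into one of three outcomes from its global
gamma pass rate — pass (optimal) at >= 95%, pass (action) at >= 90%, out of
tolerance below 90% — with hard upper limits on the isodose DTA (> 3.0 mm
for soft tissue and lung, > 2.0 mm at the spine PTV/cord interface) and on
the point-dose difference (> 8%) that force an out-of-tolerance outcome
regardless of the gamma result.  Boundary values pass: gamma exactly 95 is
optimal, a DTA of exactly 3.0 mm and a point difference of exactly 8% are
within tolerance.

Out-of-tolerance plans are tagged with a failure mode by simple rules over
the recovered metrics (uniform large displacement -> IGRT mismatch; in-PTV
dose offset -> in-volume difference low/high; excess out-of-field dose).
Cohorts aggregate outcome and failure-mode percentages (round-half-up to one
decimal), metric summary statistics and pooled-variance two-sample t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoringThresholds",
    "AuditResult",
    "CohortSummary",
    "classify_outcome",
    "classify_failure_mode",
    "aggregate_cohort",
    "compare_series",
    "round_half_up",
    "percentages_from_counts",
    "FAILURE_MODES",
]

OUTCOMES = ("optimal", "action", "out_of_tolerance")

FAILURE_MODES = (
    "IGRT mismatch",
    "In-volume dose difference (low)",
    "In-volume dose difference (high)",
    "Other shift/misalignment",
    "Out of field dose (high)",
    "Fusion of structure set to planning CT",
    "Dose calculation grid size",
)


@dataclass(frozen=True)
class ScoringThresholds:
    """Audit scoring criteria; defaults are the published thresholds."""

    gamma_optimal_pct: float = 95.0
    gamma_action_pct: float = 90.0
    dta_oot_mm: float = 3.0  # soft tissue and lung
    dta_oot_interface_mm: float = 2.0  # spine PTV/cord interface
    point_oot_pct: float = 8.0
    # failure-mode tagging thresholds
    shift_mode_mm: float = 2.0
    involume_mode_pct: float = 2.5
    outfield_mode_pct: float = 5.0

    def dta_limit(self, case_id: str) -> float:
        return self.dta_oot_interface_mm if case_id == "spine" else self.dta_oot_mm


#: DTA metrics required for scoring, per case.
_DTA_METRICS = {
    "soft_tissue": ("dta_mean_lr_mm", "dta_mean_ap_mm"),
    "spine": ("dta_max_interface_ap_mm", "dta_mean_interface_lr_mm"),
    "lung": ("dta_mean_ap_mm",),
}


@dataclass
class AuditResult:
    """Scored metrics and outcome classification for one measured plan."""

    case_id: str
    metrics: dict
    outcome: str
    triggers: list = field(default_factory=list)
    failure_mode: str | None = None
    injected_mode: str | None = None
    seed: int | None = None

    def as_record(self) -> dict:
        rec = {"case_id": self.case_id, "outcome": self.outcome,
               "failure_mode": self.failure_mode, "injected_mode": self.injected_mode,
               "seed": self.seed}
        rec.update({k: v for k, v in self.metrics.items() if np.isscalar(v)})
        return rec


def classify_outcome(
    metrics: dict,
    case_id: str,
    thresholds: ScoringThresholds = ScoringThresholds(),
) -> AuditResult:
    """Classify one plan's metrics into optimal / action / out-of-tolerance.

    ``metrics`` must contain ``gamma_pass_rate_pct``, ``point_diff_local_pct``
    and the case's DTA metrics; a missing metric is an error.  The gamma band
    sets the base outcome; any DTA or point upper-limit breach (strictly
    greater than the limit, on absolute values) forces out-of-tolerance.
    """
    required = ("gamma_pass_rate_pct", "point_diff_local_pct") + _DTA_METRICS.get(case_id, ())
    if case_id not in _DTA_METRICS:
        raise KeyError(f"unknown case id {case_id!r}")
    missing = [k for k in required if k not in metrics or metrics[k] is None]
    if missing:
        raise KeyError(f"missing scored metrics for {case_id}: {missing}")

    triggers = []
    gamma = metrics["gamma_pass_rate_pct"]
    if gamma >= thresholds.gamma_optimal_pct:
        outcome = "optimal"
    elif gamma >= thresholds.gamma_action_pct:
        outcome = "action"
    else:
        outcome = "out_of_tolerance"
        triggers.append("gamma_pass_rate_pct")

    limit = thresholds.dta_limit(case_id)
    for key in _DTA_METRICS[case_id]:
        if abs(metrics[key]) > limit:
            outcome = "out_of_tolerance"
            triggers.append(key)
    if abs(metrics["point_diff_local_pct"]) > thresholds.point_oot_pct:
        outcome = "out_of_tolerance"
        triggers.append("point_diff_local_pct")

    return AuditResult(
        case_id=case_id,
        metrics=dict(metrics),
        outcome=outcome,
        triggers=triggers,
        injected_mode=metrics.get("injected_mode"),
        seed=metrics.get("seed"),
    )


def classify_failure_mode(
    result: AuditResult,
    thresholds: ScoringThresholds = ScoringThresholds(),
    injected: str | None = None,
) -> tuple[str, bool | None]:
    """Tag an out-of-tolerance plan with a failure-mode category.

    Rule order: a uniform-direction displacement beyond 2 mm (recovered from
    the per-edge DTA displacements) is an IGRT mismatch; a large non-uniform
    displacement is some other shift/misalignment; a mean in-PTV global dose
    difference beyond +/-2.5% is an in-volume dose difference (positive =
    plan exceeds measurement = delivered low); an out-of-field measured
    excess beyond 5% of prescription is out-of-field dose (high); otherwise
    unclassified.  When the injected ground-truth mode is known the second
    return value reports agreement.
    """
    if result.outcome != "out_of_tolerance":
        raise ValueError("failure modes are only assigned to out-of-tolerance plans")
    m = result.metrics
    mode = "unclassified"

    edges = m.get("edge_displacements", {})
    axis_shift = {}
    uniform = True
    for axis, (lo, hi) in edges.items():
        axis_shift[axis] = -(lo + hi) / 2.0
        if abs(lo) > 0.5 and abs(hi) > 0.5 and lo * hi < 0:
            uniform = False
    shift_mag = math.hypot(*axis_shift.values()) if axis_shift else 0.0
    big_edges = [e for pair in edges.values() for e in pair if abs(e) > thresholds.shift_mode_mm]

    involume = m.get("ptv_global_diff_pct")
    outfield = m.get("outfield_excess_pct")

    if axis_shift and uniform and shift_mag > thresholds.shift_mode_mm:
        mode = "IGRT mismatch"
    elif big_edges:
        mode = "Other shift/misalignment"
    elif involume is not None and involume > thresholds.involume_mode_pct:
        mode = "In-volume dose difference (low)"
    elif involume is not None and involume < -thresholds.involume_mode_pct:
        mode = "In-volume dose difference (high)"
    elif outfield is not None and outfield > thresholds.outfield_mode_pct:
        mode = "Out of field dose (high)"

    result.failure_mode = mode
    injected = injected if injected is not None else result.injected_mode
    agrees = None if injected in (None, "none") else (mode == injected)
    return mode, agrees


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention of the printed tabulations)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentages_from_counts(counts: dict, total: int | None = None, decimals: int = 1) -> dict:
    """Percentages of a count breakdown, round-half-up to ``decimals``."""
    total = total if total is not None else sum(counts.values())
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: round_half_up(100.0 * v / total, decimals) for k, v in counts.items()}


@dataclass
class CohortSummary:
    """Aggregated outcomes, failure modes and metric statistics."""

    n_total: int
    case_counts: dict  # case_id -> n plans
    outcome_counts: dict  # case_id -> {outcome: n}
    outcome_pct: dict  # case_id -> {outcome: %}
    failure_mode_counts: dict  # mode -> n (over all OOT plans)
    failure_mode_pct: dict  # mode -> % of failures
    metric_stats: pd.DataFrame  # per case x metric: mean, sd, median, q1, q3

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for case, per in self.outcome_pct.items():
            row = {"case_id": case, "n": self.case_counts[case]}
            row.update({f"{k}_pct": v for k, v in per.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def aggregate_cohort(results: list[AuditResult]) -> CohortSummary:
    """Aggregate per-plan audit results into a cohort summary.

    Outcome percentages are per case; failure-mode percentages are over the
    total number of out-of-tolerance plans; counts are conserved across both
    breakdowns.  Metric statistics cover mean, SD, median and quartiles.
    """
    if not results:
        raise ValueError("empty cohort")
    known = set(_DTA_METRICS)
    bad = {r.case_id for r in results} - known
    if bad:
        raise ValueError(f"unknown case ids in cohort: {sorted(bad)}")

    df = pd.DataFrame([r.as_record() for r in results])
    case_counts = df["case_id"].value_counts().to_dict()
    outcome_counts = {}
    outcome_pct = {}
    for case, sub in df.groupby("case_id"):
        counts = {o: int((sub["outcome"] == o).sum()) for o in OUTCOMES}
        outcome_counts[case] = counts
        outcome_pct[case] = percentages_from_counts(counts)

    failures = df[df["outcome"] == "out_of_tolerance"]
    fm_counts = {}
    if len(failures):
        vc = failures["failure_mode"].fillna("unclassified").value_counts()
        fm_counts = {k: int(v) for k, v in vc.items()}
    fm_pct = percentages_from_counts(fm_counts, total=len(failures)) if fm_counts else {}

    metric_cols = [c for c in df.columns if c.endswith(("_pct", "_mm")) and c != "case_id"]
    stats_rows = []
    for case, sub in df.groupby("case_id"):
        for col in metric_cols:
            vals = sub[col].dropna()
            if not len(vals):
                continue
            stats_rows.append(
                {
                    "case_id": case,
                    "metric": col,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "median": vals.median(),
                    "q1": vals.quantile(0.25),
                    "q3": vals.quantile(0.75),
                    "n": len(vals),
                }
            )
    return CohortSummary(
        n_total=len(df),
        case_counts=case_counts,
        outcome_counts=outcome_counts,
        outcome_pct=outcome_pct,
        failure_mode_counts=fm_counts,
        failure_mode_pct=fm_pct,
        metric_stats=pd.DataFrame(stats_rows),
    )


def compare_series(a, b, alpha: float = 0.05) -> dict:
    """Two-sample pooled-variance t-test between two metric series.

    Returns the t statistic, the two-sided p value on ``n_a + n_b - 2``
    degrees of freedom and a significance flag at strictly ``p < alpha``.
    Zero pooled variance is degenerate: equal means give ``t = 0, p = 1``;
    unequal means are flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each series needs at least 2 values")
    pooled = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
    if pooled == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return {"t": 0.0, "p": 1.0, "significant": False, "degenerate": True}
        return {"t": float("inf") * np.sign(a.mean() - b.mean()),
                "p": 0.0, "significant": True, "degenerate": True}
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "p": float(p), "significant": bool(p < alpha), "degenerate": False}
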