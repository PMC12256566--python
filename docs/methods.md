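# Methods

This package implements the analysis chain of an end-to-end SBRT dosimetry
audit: a radiochromic film measured in an anthropomorphic thorax phantom is
calibrated, corrected, registered to the treatment plan, compared by gamma
and distance-to-agreement (DTA) metrics, and scored into a three-tier
outcome with failure-mode tagging. Because the audit's facility
measurements are not public, the package also contains a first-class
synthetic-data generator that emulates the three audit cases with known
injected delivery errors, so every stage is testable end to end.

## The audit cases

Three cases are modelled on one film plane each, all scored per fraction
(the audit measures a single delivery; prescription per fraction =
prescription / fractions):

| case | prescription | PTV geometry | coverage | notable constraints |
|---|---|---|---|---|
| soft tissue | 45 Gy / 3 fx | 2.5 cm cylinder | >= 95% | max dose 110-140% |
| spine | 24 Gy / 2 fx | vertebra + 2 mm, excluding cord PRV | >= 80% | cord PRV <= 14 Gy, esophagus <= 18 Gy (0.03 cc) |
| lung | 48 Gy / 4 fx | 2 cm sphere + 1 cm margin | >= 98% | max dose 110-140% |

All cases require planar conformity indices CI100 <= 1.2 and CI50 <= 5.0,
computed here as isodose-area over PTV-area on the film plane (a 2D
surrogate of the volumetric index; the scoring protocol does not print a
formula, so the trial-convention area ratio was adopted and is exposed in
the API).

## Synthetic planned dose

The planned dose is an analytic model chosen for differentiable profiles
and closed-form isodose radii:

    D(r) = P * Rx_fx * f(r) + F * Rx_fx * (1 - f(r)),
    f(r) = 1 / (1 + exp((r - R) / s))

with plateau fraction `P = 1.20` (inside the required 110-140% window and
low enough that a +10% delivery error stays inside the 0-20 Gy film
calibration range), logistic penumbra scale `s` set by an 80-20% width of
3 mm, and an out-of-field scatter/leakage floor `F = 0.05` (real deliveries
leave a low-dose bath outside the field; the floor is what makes genuine
out-of-field dose errors visible to gamma, exactly as in measured data).
The plateau radius `R` is the PTV radius + 2.5 mm (2.0 mm for spine).

The spine case multiplies the plateau term by a logistic trough in distance
`d` to the cord centre, `g(d) = g0 + (1 - g0) * logistic((d - d0) / w)`
with floor `g0 = 0.33`, midpoint `d0 = 7.56 mm` and width `w = 1.31 mm`,
solved so that the cord PRV stays below 7 Gy per fraction while PTV
coverage remains >= 80% (the case is deliberately the hardest to plan; the
default plan covers ~82%). The phantom geometry (vertebral body with
cortical shell and trabecular interior, cord canal, anterior esophagus
disc) is representative of the physical phantom, not a replica — the
as-built drawings and pin positions are not published.

Every generated plan is verified against its own case constraints by the
metrics module (`verify_plan_constraints`); the generator refuses nothing
silently.

## Film model and calibration

The forward film model maps dose to net optical density per RGB channel:

    netOD_ch(D, t) = a_ch * D / (1 + b_ch * D) * (1 + c_ch * ln(t / t_ref))

a saturating rational response (strictly increasing on 0-20 Gy, zero at
zero dose) with logarithmic post-irradiation darkening relative to the
calibration scan time. Default sensitivities make red the most sensitive
channel, as for EBT3-class film; scanner noise is Gaussian in netOD
(sigma 0.002), which propagates to ~0.4% dose noise at 12 Gy after
three-channel combination — comfortably inside the audit's stated +/-2.5%
(k=1) film uncertainty.

Calibration fits the same rational family per channel by least squares
(12 levels, 0-20 Gy, including zero). The functional form is pluggable; a
`dose = p1*netOD + p2*netOD^p3` power form is registered as an alternative.
The rational family is the default because it shares the generator's form,
giving an analytic monotone inverse and an exact round trip — the
generator and corrector deliberately share the darkening form as well, so
the correction is exact by construction and the whole chain is validated by
round-trip tests rather than by fitting error.

Dose conversion applies the darkening correction, inverts each channel,
combines channels by inverse-variance weights (scanner noise propagated
through each channel's sensitivity), masks pixels outside the calibrated
netOD range, and multiplies by the check-film session scale factor. The
check-film QC fits a single through-origin least-squares factor mapping
calibrated film dose onto chamber dose for the two session films; the
factor is exposed, `|factor - 1| <= 5%` is accepted (the limit names the
boundary, so exactly 5% passes), and a failed QC refuses conversion with a
"rescan required" signal.

## Registration

Manual film-to-CT alignment is replaced by a scriptable equivalent:
least-squares rigid registration (2D orthogonal Procrustes, no scale) of
fiducial cut-out landmarks. The dual-observer workflow is modelled as two
independent landmark sets; agreement is the worst-case discrepancy of the
two transforms over the four film corners (the worst points for a rotation
difference) with the < 0.5 mm audit tolerance. Resampling onto the plan
grid is bilinear with out-of-film pixels masked invalid — the same
interpolation used everywhere else in the pipeline.

## Gamma and DTA

Global gamma uses 5%/2 mm criteria normalized to the per-fraction
prescription with a 10% low-dose threshold applied to the measured dose;
gamma is evaluated at measured-film pixels (the audit scores the
measurement) searching the planned distribution, bilinearly interpolated on
a 0.2 mm offset lattice inside a 3x-DTA search radius. Offsets are visited
in order of increasing radius with exact early termination (an offset at
radius r cannot improve a pixel whose current gamma^2 is below (r/dta)^2).
Boundary pixels whose search disc leaves the planned grid are invalid, not
failed.

`gamma_oracle` is the validation route: per-pixel exhaustive search over
planned grid nodes inside the same radius, with no subsampling, pruning or
early termination. Equivalence tests align the candidate sets — engine at
subsample = grid pitch against the node oracle, and engine at 0.25 mm
against the oracle on a bilinearly upsampled reference — so the check
isolates the search logic itself; analytic scenarios (flat 10% offset,
single hot pixel, pure translations) pin the absolute values.

1D DTA finds linear-interpolated crossings of the 70% isodose (70% of the
per-fraction prescription, consistent with the global normalization) on
horizontal (L-R) and vertical (A-P) profiles, pairs planned and measured
crossings by proximity, and reports signed displacements as planned minus
measured (so an injected +s shift reads -s; the sign convention mirrors
the dose-difference definitions). The spine variant scores the maximum
signed displacement over A-P profiles sampled across the PTV/cord
interface, plus the L-R mean through the cord centre; the lung case scores
A-P only (in the physical set-up a film pin obstructs the L-R isodose).

Dose differences follow the audit definitions: local
`(planned - measured)/measured`, global
`(planned - measured)/(prescription per fraction)`, at the diamond-detector
point and as means over regions (film-plane PTV = area bound by the
prescription isodose; spinal-cord ROI = central 6 mm disc).

## Medium corrections

Film and point readings in bone or lung materials are converted to the
plan's reporting mode (Dm,m or Dw,w) by per-material multiplicative
`k_med` factors from a user-suppliable table; Dw,m is unsupported (no such
plans exist in the audited cohort). The shipped defaults are unity apart
from a 0.992 water-to-tissue factor on plastic-water film regions of the
soft-tissue and spine cases (per the reporting guidance followed by the
audit; lung plastic regions deliberately receive none). Campaign-specific
`k_med` values are measurement-derived and must be supplied for real data;
synthetic tests embed known factors so correctness is verified regardless
of their numeric values.

## Scoring and cohorts

The gamma pass rate sets the outcome band (>= 95% optimal, >= 90% action,
< 90% out of tolerance) and hard upper limits force out-of-tolerance
regardless of gamma: |DTA| > 3.0 mm (soft tissue, lung) or > 2.0 mm (spine
interface), |point difference| > 8%. Boundaries are inclusive on the pass
side (gamma exactly 95 is optimal; DTA exactly 3.0 and a point difference
of exactly 8% pass) — the published criteria use ">=" for the bands and
">" for the limits.

Failure-mode tagging is a rule-based operationalization of what is a human
post-audit analysis in practice: a uniform-direction displacement beyond
2 mm (recovered from per-edge DTA displacements) is an IGRT mismatch; a
large non-uniform displacement is some other shift/misalignment; a mean
in-PTV global difference beyond +/-2.5% is an in-volume dose difference
(positive = plan exceeds measurement = delivered low); a measured
out-of-field excess beyond +5% of prescription is out-of-field dose
(high); anything else is unclassified. All thresholds are config-exposed.
A pure rotation of the circularly symmetric soft-tissue or lung field is
not identifiable from dose alone; the "other shift" preset is therefore
not part of the recovery guarantees.

Cohort aggregation reports outcome percentages per case and failure-mode
shares over all failures, rounded half-up to one decimal. Note two
published tallies (13/60 printed as 21.6% and 25/60 as 41.6%) are not
round-half-up values (21.7/41.7); this package keeps the round-half-up
convention and does not imitate the truncation. Series comparisons use the
pooled-variance two-sample t-test with two-sided p on n1+n2-2 degrees of
freedom and strict p < 0.05 significance; zero pooled variance is handled
degenerately (equal means: t = 0, p = 1).

## End-to-end simulation

`simulate_audit` chains everything for one plan: phantom and plan,
perturbed delivery (seeded shift / rotation / global / in-field /
out-of-field scaling / dose noise), film exposure and scanning with a
per-session multiplicative scanner drift (sigma 2.23%, chosen so ~2.5% of
sessions trip the 5% check-film limit, matching the observed rescan rate;
a tripped QC triggers an automatic re-scan with a fresh drift draw),
random scanner film placement registered back through the fiducials by two
observers, medium corrections, an independently noisy point-detector
reading (1.5% repeatability), metrics and scoring. The generator divides
the embedded medium factors out of the film's absorbed dose so that the
corrector restores the reported quantity exactly — the invariant a real
correction chain is supposed to satisfy.

All randomness derives from one integer seed per plan through
`numpy.random.SeedSequence` spawn keys; identical seeds give bit-identical
results.

### What the synthetic data does and does not show

The generator reproduces the *structure* of the measurement problem —
plateau/penumbra dose shapes, film response and darkening, session scale
drift, registration noise, medium factors, injected failure classes — with
parameters at the magnitudes the audit reports (film noise within the
+/-2.5% budget, 2.5% QC trip rate, sub-0.1 mm observer noise). It does not
reproduce TPS-algorithm-specific dose errors, scanner lateral-response
artifacts, film batch variation, or motion; passing tests demonstrate the
correctness of the analysis chain and the recoverability of injected error
modes, not the clinical accuracy of any planning system. The published
per-algorithm cohort statistics derive from 782 facility measurements that
are not public and are not reproduced here; only tabulations derivable
from printed counts are recomputed.

## Problem sizes and numerical choices

Defaults: 200 x 200 grid at 0.5 mm (100 mm film plane), pixel-centre
coordinates with the origin at the plane centre. The test suite and the
acceptance script use 160 x 160 for end-to-end cohorts and 101 x 101 for
oracle comparisons — sizes at which the whole suite completes in well
under a minute per hundred simulated plans while every geometric feature
(penumbra, cord trough, search radii) remains resolved by >= 2 pixels.
Gamma subsampling is 0.2 mm (<= dta/10); crossings and registrations are
exact to floating point on noiseless inputs. Ties and degenerate inputs:
collinear landmarks are rejected; profiles that never cross the isodose
level raise with the failing side named; an empty gamma-valid region is an
error rather than a vacuous 100%.

## Known limitations

* 2D only: out-of-plane errors are invisible, as in the single-film audit.
* The planar CI and OAR "max to 0.03 cc" checks are film-plane surrogates
  of volumetric criteria.
* Failure-mode rules are deterministic stand-ins for expert judgement; the
  two modes that require planning-system context (structure-set fusion,
  dose-grid size) can be injected as labels but never recovered from dose.
* `k_med` values ship as placeholders; real use requires a measured table.
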