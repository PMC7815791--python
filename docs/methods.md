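# Model and methods

## Scope

`psa-mri-sim` is a cohort microsimulation for comparing two prostate-cancer
screening pathways after a positive PSA test (cut-off 3 ng/mL): direct
TRUS-guided biopsy (the *regular* pathway) versus mpMRI triage followed by
MRI-guided biopsy in mpMRI-positive men only (the *MRI* pathway).  The
package owns the full pipeline: demography, natural history, screening
overlay, treatment and mortality, per-1000 outcome accounting, and the
tornado/threshold sensitivity analyses.  It deliberately does **not**
calibrate to registry incidence, fit survival to registry data, or model
costs or probabilistic parameter uncertainty.

## Natural history

Each man can enter a preclinical, screen-detectable disease state at an
age drawn from a Weibull onset model, cumulative hazard
`H(a) = (a/scale)^shape` (defaults: shape 5.5, scale 105 years; onsets at
or beyond age 100 are treated as never detectable — nothing downstream can
depend on them once the age exceeds the life table's closure).  Entry is
into the T1, non-metastatic layer with a configurable Gleason mix
(defaults: <7 with 0.75, =7 with 0.18, >7 with 0.07), so grade
heterogeneity exists from onset and grade-specific test sensitivities have
non-degenerate consequences.

The state space is the 3 × 3 × 2 cross product of T stage (T1–T3), Gleason
class (<7, =7, >7) and metastasis (M0/M1) — 18 states.  Progression is
semi-Markov with exponential sojourns and three transition kinds per state
(T up one level, Gleason up one level, M0→M1), each with a per-state
configurable rate; severity never decreases.  From every state an
exponential clinical-diagnosis clock competes with the progression clocks.
Defaults: T-up 0.10/yr, Gleason-up 0.06/yr, metastasis 0.008–0.09/yr
rising with grade and stage; clinical diagnosis 0.03/0.08/0.15 per year
for T1/T2/T3 and 0.45 once metastasised.

Two conventions matter downstream:

* the trajectory is **not truncated at death** — the counterfactual
  clinical-diagnosis age, even past the man's other-cause death, defines
  overdiagnosis (screen-detected and `dx_age` absent or after death);
* all ages are continuous years from birth on a single axis.

## Demography

Other-cause death ages come from an annual life table (`age,qx`)
understood as all-cause-minus-prostate-cancer mortality, inverted by a
single uniform draw with uniform positioning inside the death year; the
final `qx` must be 1, so every man has a finite death age.  The packaged
table (`data/synthetic_life_table.csv`) is a Gompertz–Makeham synthetic
stand-in, hazard `3e-4 + 3e-5·e^{0.092a}`, closed at age 100; its life
expectancy at birth is ≈ 79.9 years.

## Screening overlay

Invitations run from age 55 to 64 every 3 years ([55, 58, 61, 64]);
attendance is an independent 80% Bernoulli per man per round, and a
negative episode carries no memory.  PSA positivity is a per-state episode
probability (defaults 0.50/0.72/0.88 by T stage with +0.05/+0.10 grade
bumps); no continuous PSA level is modelled.  An attended episode detects:

* regular: `u_psa < p_state` and `u_comp < 0.90` and `u_bx < 0.90`;
* MRI: additionally `u_mri < mpMRI sensitivity` (0.94 high grade, 0.74 low
  grade) and the biopsy uses MRIGB sensitivity (0.91 high, 0.44 low).

mpMRI uptake among PSA-positive men is 100%; the 90% compliance applies at
the biopsy step in both pathways.  Screens stop at the earlier of clinical
diagnosis and death; clinical presentation is detected with certainty in
every arm, with TRUSGB grading characteristics.  Grade misclassification
is downgrade-only and applies at every biopsy: 36.3% on the TRUSGB route
(screen or clinical), 8.7% on the MRIGB route.  Counting uses the
*recorded* grade, which is what makes the misclassification gap
consequential in the significant/insignificant rows.

Biopsy counts are expected values derived from detections and the biopsy
positive predictive values (screen 22.7% regular, 58% MRI; clinical
35.8%), never rounded before per-1000 scaling — the simulator carries no
PSA false positives, so negative biopsies exist only through this PPV
scaling.

## Treatment, mortality, cure

Treatment (RP, RT, AS, palliative) is drawn from an assignment table
indexed by age band (</≥ 70), T stage, *recorded* grade and metastasis;
M1 is always palliative.  Survival after clinical diagnosis is exponential
per (true grade, metastasis) — a declared parametric stand-in (defaults:
rates 0.02/0.085/0.25/0.33 for low-M0/high-M0/low-M1/high-M1) — with RP
and RT acting as a proportional hazard 0.56 (survival draw divided by the
ratio); AS and palliative are survival-neutral.  Because assignment uses
the recorded grade while survival uses the true state, a downgraded
high-grade cancer is undertreated in the utility accounting, though not in
survival (see limitations).

Screening's only mortality pathway is the lead-time-dependent cure: a
screen-detected non-metastatic man is cured with probability
`c(L) = c_max(1 − e^{−λL})` (defaults `c_max` 0.85, `λ` 0.25/yr; a cure
for screen-detected M1 disease is off by default but configurable).  The
survival uniform is drawn once per man and shared across arms, so an
uncured man dies on exactly his no-screening date — deaths averted are
non-negative man by man, and `c ≡ 0` makes the arms identical.

## Common random numbers

Every draw is taken from a purpose-keyed stream (`(master_seed, purpose)`
for fixed-size purposes, rows indexed by man id; `(master_seed, purpose,
man id)` substreams for the variable-length natural history).  All three
arms consume the same attendance, PSA, compliance, biopsy,
misclassification, treatment, survival and cure uniforms; the mpMRI
uniform is drawn for every man whether or not the MRI arm uses it.  Adding
or reordering arms therefore cannot change any draw, and setting the two
pathways' parameters equal makes their outcomes bit-identical.

## QALY accounting

Utility losses are `(1 − utility) × duration`, truncated at death.
Per-man events: screening attendance (0.99, 1 wk), mpMRI (0.96, 1 wk — the
published estimate), diagnosis (0.80, 1 mo), treatment (RP 0.67 and RT
0.73 for 2 mo, AS 0.97 for 7 yr, palliative 0.60 for 2.5 yr) and, for
prostate-cancer deaths, palliative therapy (30 mo) and terminal illness
(0.40, 6 mo) anchored before death.  MRIGB's disutility is defined as half
of TRUSGB's (0.90, 3 wk) at the same duration.  Biopsy disutility is
applied at the aggregate level on the PPV-scaled expected biopsy counts,
since per-man negative biopsies are not simulated; mpMRI disutility counts
simulated PSA-positive episodes, i.e. disease-bearing men only — the
omitted scans of healthy PSA-positive men cost ≈ 0.0008 QALY each, well
below every reported difference.  QALYs are life-years minus utility loss,
undiscounted, with life-years counted from birth (only differences between
arms are reported, so the origin cancels).

## Reporting conventions

`difference` is the magnitude `|regular − mri|`; `percent_change` is
signed by `mri − regular` with magnitude `|regular − mri| / max(regular,
mri) × 100` — the one convention consistent with every published row
(the published "+3%" for life-years gained per death averted is
inconsistent with its own inputs, ≈ 1.3% under any convention, and is
excluded from the reproduced rows; "+3.9%" vs a computed 3.99% is treated
as source rounding noise).  The harm–benefit ratio is overdiagnosed cases
per death averted; when deaths averted are non-positive it is reported as
NaN rather than raising.  The matched missed-significant percentage is
man-level: of men with a recorded-significant screen detection in the
regular arm, the share without one in the MRI arm.

## Sensitivity analyses

The tornado analysis reruns the paired simulation at the endpoints of the
published 95% CI/ranges of the four MRI-pathway sensitivities (mpMRI high
0.70–0.97, mpMRI low 0.66–0.81, MRIGB low 0.26–0.64, MRIGB high
0.87–0.94), same seed throughout, reporting the MRI harm–benefit ratio.
The threshold analysis applies a *relative* simultaneous transformation —
low-grade sensitivities × (1 + δ) capped at 1, high-grade × (1 − δ) — and
scans QALYs gained per death averted; δ = 0.14 maps the four baseline
sensitivities to 81%, 78%, 84% and 50%, which is what fixes the relative
(not absolute) reading.  The crossing is located by linear interpolation
of the metric difference's sign change.

A caution on directions: the intuition "higher high-grade sensitivity ⇒
lower harm–benefit ratio" assumes overdiagnosis is essentially low-grade.
Whenever a model produces non-negligible *high-grade* overdiagnosis
(high-grade screen detections in men who die of other causes before their
clinical diagnosis), raising a high-grade sensitivity raises both the
numerator and the denominator and the ratio's direction becomes
parameterization-dependent; on the synthetic defaults it in fact rises
slightly.  What is guaranteed man-by-man under common random numbers — and
what the tests assert — is the coupling: significant detections and deaths
averted are non-decreasing in any high-grade sensitivity, and across the
threshold grid recorded-significant detections and deaths averted fall
while truly-low-grade screen detections rise.  Under the synthetic
defaults the MRI pathway's QALYs per death averted stays ahead of the
regular pathway over the whole δ grid (no crossing); the published 14%
crossing point is a property of the unpublished calibrated
parameterization, not of the transformation arithmetic.

## Synthetic parameterization: what it does and does not show

The generator (`synthetic.default_config`) carries every published test
characteristic at its reported value and fills everything unpublished —
onset, progression, diagnosis rates, life table, PSA positivity, treatment
mix, baseline survival, cure parameters, non-mpMRI utilities — with the
documented defaults above, chosen once for epidemiological plausibility
(lifetime detection ≈ 13%, prostate-cancer mortality ≈ 6% of men,
screen detection concentrated at ages 55–64) and for non-degeneracy
(detections in both grade classes, some overdiagnosis, some deaths
averted at n ≈ 10^5).  Passing tests therefore demonstrate the *mechanics*
— coupling, accounting identities, direction of pathway effects, exact
derived arithmetic — not the absolute per-1000 magnitudes of any real
population; the synthetic cohort produces less overdiagnosis relative to
detection than the calibrated analysis (its clinical-diagnosis hazards are
comparatively fast), which is why its harm–benefit ratios sit below 1.

## Numerical and testing choices

Default desk-run cohort is 10^5 men (a paired three-arm evaluation takes
seconds to tens of seconds); per-1000 scaling is linear in the simulated
n, which is recorded in all outputs alongside the seed and a configuration
hash.  Monte-Carlo assertions use 4-standard-error bands against closed
forms (competing exponentials, Bernoulli products, the Weibull median, the
analytic toy model; the toy's deaths-averted expectation uses numerical
quadrature of its closed-form integrand).  Categorical draws invert
explicit CDFs in fixed orders (states in enumeration order; treatments RP
< RT < AS < palliative).  Progression is abandoned past age 150 with the
diagnosis age left absent — indistinguishable from any later diagnosis for
every reported quantity.  Degenerate inputs are contracts, not crashes:
zero onset hazard yields empty histories, zero attendance reproduces the
no-screening arm, zero PPVs are configuration errors only when detections
exist, and a non-positive deaths-averted denominator yields the NaN
sentinel.

## Known limitations

* No PSA level or PSA false positives: healthy men never screen positive,
  so biopsy harms in healthy men enter only through PPV scaling and their
  mpMRI disutility is omitted (bounded above, ≈ 0.2 QALY per 1000).
* Exponential sojourns and baseline survival are stand-ins; real dwell
  and survival distributions are not exponential.
* The cure mechanism is independent of assigned treatment, so grade
  misclassification affects treatment mix and QALYs but not mortality;
  in a model where undertreatment raised mortality, the MRI pathway's
  mortality advantage would grow.
* Detection counts accumulate over the whole lifetime (screen plus
  clinical presentation), matching the published table's note that its
  rows contain both screen-detected and interval cancers.
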