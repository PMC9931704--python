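# Methods

This note documents the model, the choices behind it, and what the package's
tests do and do not demonstrate.

## Scope and design of the disposition model

The analysis this package implements was originally carried out on a
commercial whole-body PBPK platform whose organ-level physiology and compound
file are not public.  The verifiable outputs of such an analysis — scaled
clearances, exposures, NCA parameters, fold-error statistics — depend on
dose, clearance scaling and the linearity of disposition, not on the organ
topology.  The package therefore implements a *reduced* disposition model: a
gut depot with first-order absorption (rate `ka`, bioavailable fraction `fa`,
optional lag) feeding a central compartment that exchanges with one
peripheral compartment and is cleared from the central compartment.  Amounts
are in mg, volumes in L, clearances in L/h; concentrations leave the model in
ng/ml (the mg→ng factor 1e6 enters only at the NCA boundary, via
`CL/F = dose·1e6/AUC` reported in L/h).

Absolute concentration curves from this reduced model are approximations;
quantities that depend only on dose, clearance and linearity (AUC, CL/F,
fold-error algebra, accumulation, stage orderings) are exact consequences of
the stated parameters and are what the tests pin down.

## Clearance scaling

Adult reference clearances: systemic `CL_iv` 49.5 L/h, renal `CL_R` 22.2 L/h,
leaving 27.3 L/h of additional (non-renal) elimination.  Scaling to a subject:

* **Size.** Both pathways scale allometrically with weight, exponent 0.75
  (the conventional clearance exponent; the source analysis states only
  "allometrically scaled").  No enzyme or transporter ontogeny is applied.
* **Kidney function.** Renal clearance is multiplied by `GFR/120`, tying the
  renal pathway proportionally to filtration; this encodes the assumption
  that renal elimination follows the same developmental and disease
  trajectory as GFR.
* **Disease.** Non-renal clearance retains a stage-dependent fraction: 1.0
  healthy, 0.8 mild, 0.6 severe (from the adult CKD parameterization), with
  0.7 for moderate chosen by linear interpolation and overridable in
  configuration.  End-stage disease is deliberately unsupported — no
  parameterization exists for it here and dialysis is out of scope.

The additivity `CL_iv = CL_R + CL_additional` is enforced at construction
(tolerance 1e-9).

## Disease overlays beyond clearance

CKD also shifts hematocrit (renal anemia), plasma protein binding and gastric
emptying.  The source analysis states that these were incorporated but not
their magnitudes, so the defaults here are conventions chosen once:
hematocrit −0.02/−0.04/−0.06 for mild/moderate/severe, unbound-fraction
multipliers 1.05/1.10/1.15, gastric-emptying multipliers 1.1/1.2/1.3 (slowing
absorption by dividing `ka` and stretching the lag), and a Kp multiplier of
1.0.  All are configuration-overridable under `disease:`.  In the lumped
model the binding and hematocrit changes are bookkeeping on the subject (they
do not feed back into clearance, which is specified directly as total
clearances); the gastric-emptying and Kp multipliers do affect the simulated
curve shape.

## Other compound parameters

Captopril absorption/distribution defaults (literature-typical, not outputs
of the reproduced analysis): `fa` 0.65, `ka` 1.5 h⁻¹, lag 0 h, `Vss` 0.8 L/kg,
`fu_plasma` 0.70, Kp scalar 1.0.  The lumped-model shape parameters —
`central_fraction` 0.5 (how Vss splits) and `q_adult` 20 L/h
(inter-compartmental clearance, allometrically scaled) — control the
biexponential shape only; AUC and CL/F are invariant to them.  Oral
bioavailability equals `fa` (no separate first-pass term), so for a complete
AUC the simulated `CL/F` equals `CL_iv/fa`, which is used as an internal
consistency check.

## Virtual populations

`sample_population` emulates a matched virtual cohort: with a reference
subject, age, sex and weight (the dose-relevant covariates) are fixed and
physiology is resampled — height (log-normal CV 4% around a piecewise-linear
growth approximation), hematocrit (CV 5% around 0.37), unbound fraction
(CV 10% around 0.70), and GFR (log-normal CV 15% around the reference value,
truncated to the reference's stage band; uniform within the band when no
reference GFR exists).  Without a reference, ages are uniform in the
requested range, sex is Bernoulli, and weight is log-normal (CV 15%) around a
piecewise median-weight-for-age approximation (3.4 kg at birth, 10 kg at 1 y,
22 kg at 6 y, 43 kg at 13 y, plateau 70 kg).  The source analysis does not
report the variability its simulator applied, so these CVs are conventions:
central tendencies of simulated cohorts are comparable across
implementations, dispersion is not.

Body surface area uses the Haycock formula (0.024265·W^0.5378·H^0.3964),
validated across pediatric sizes, with DuBois behind a flag.  Healthy GFR
follows a two-point maturation curve — 20 ml/min/1.73 m² at birth, linear to
120 by age 1, flat thereafter — because those are the two published anchors;
no finer neonatal maturation is modelled.  GFR under 15 years comes from this
BSA/maturation route; at 15 years and older the Jelliffe creatinine equation
`(98 − 0.8·(age − 20))/Scr` (×0.9 for females, clamped at 0) is used.  The
reference table's printed pediatric eGFRs cannot be reproduced from that
equation (the source studies most likely used a Schwartz-type formula), so
packaged eGFRs are treated as given data, never as outputs to reproduce.

### CKD staging boundaries

The printed bands are half-open at the top (e.g. mild 60 − <90) with healthy
strictly above 90, which leaves the boundary values 90/60/30 formally
unassigned; this package assigns each to the band below it (90 → mild,
60 → moderate, 30 → severe) while 15 remains severe's lower edge (end-stage
is GFR < 15).  The bands then partition [0, ∞) exactly, which is
property-tested.

## Numerical integration

Between dose events the model is a linear time-invariant ODE, so the default
integrator propagates the state with the matrix exponential — exact to
machine precision, with the step matrix cached per step size.  This makes
dose-linearity of the solution exact rather than solver-limited.  An adaptive
stiff solver (LSODA, rtol 1e-8, atol 1e-10) is available via
`integrator="lsoda"` and is cross-checked against the exact path in the test
suite.  Steady state is declared when the dosing-interval AUC (trapezoid on a
240-point grid) changes by < 0.1% between consecutive doses, with a 90-day
cap (the clinical steady-state study sampled after three months) and a logged
warning on non-convergence.  The q8h interval for steady-state simulations is
standard pediatric captopril practice; the source study does not state it.

## NCA conventions

Linear trapezoidal AUC by default (log-down by flag) because the reference
table's `dose/AUC = CL/F` identities hold exactly under the linear rule, and
`CL/F` divides by AUC_0−t rather than AUC_0−∞ for the same reason (flag to
switch).  λz is an unweighted least-squares fit on ln C over the last k ≥ 3
post-peak points, k chosen by adjusted R²; AUC_0−∞ adds `C_last/λz` and is
omitted (with a warning, not an error) when no declining terminal phase
exists.  C_max ties resolve to the earliest time.

## Evaluation metrics

Fold error is predicted/observed — the reference analysis's equation label
and body disagree on the direction, and the body (predicted/observed) is the
only reading consistent with every reproducible table ratio.  AFE is the
geometric mean `10^(mean log₁₀ ratio)`.  The mean-ratio CI is normal-theory t
on the raw ratio scale (log-scale by flag); the percentile bands use linear
interpolation between order statistics so small-n bands are reproducible.
Prediction-interval coverage counts observed points inside the interpolated
5th–95th band.

### Fixture quarantine

Eleven printed cells of the packaged PK-parameter table fail their own
internal identities (a decimal-shifted clearance pair, two clearances that
disagree only because the predicted AUC was printed at 3 significant
figures, one AUC ratio off by 0.01, and six clearance-ratio cells).  They are
retained verbatim, listed in `table2_quarantine.json` with the recomputed
values, and excluded from parity assertions.  The printed aggregate
statistics also do not reconcile with the printed per-row ratios (the
recomputed mean AUC ratio is 1.21 and AFE 1.07); the package always reports
recomputed aggregates.

## Synthetic studies and what the tests show

`generate_study` samples a cohort, simulates noise-free truth, and multiplies
concentrations by i.i.d. log-normal errors (sd 0.2 by default — a
conventional residual magnitude for concentration assays; the reference
analysis states no error model).  Recovery tests show: with zero noise the
pipeline returns fold errors of exactly 1 against its own generating model;
with sd 0.2 and n = 50 the mean NCA-estimated CL/F stays within 3% of truth
(the ~2% downward bias is the Jensen effect of inverting a noisy AUC); and
observations drawn from the band's own population fall inside the 5th–95th
band ≈ 90% of the time.  These demonstrate internal consistency and
calibration of the machinery — not the fidelity of the reduced model to real
pediatric physiology, which would require the unavailable organ-level
parameterization.

## Problem sizes

Default study conditions mirror the reference analysis: 100 virtual subjects
per reference subject across 14 reference children, q8h steady state for the
mg/kg-dosed study and single doses for the mg-dosed study.  The exact
integrator makes this cheap (the full pipeline runs in about a second);
recovery and coverage checks use 50-subject noisy studies and 400/150-subject
band/observation cohorts.

## Known limitations

No organ-level physiology, metabolite kinetics, dialysis, IV route,
transporter ontogeny or pharmacodynamics; the two-point GFR maturation curve
is coarse below age one; disease overlays beyond clearance are conventions;
and absolute concentration predictions are approximations of the original
whole-body analysis, so only their qualitative orderings are asserted.
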