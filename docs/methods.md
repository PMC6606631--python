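# Methods

This note documents the models, numerical choices and limitations behind
`gaitnorm`, in the order data flows through the package.

## Conventions

Gait cycles are time-normalised to 101 samples; sample *k* (1..101) sits
at (*k* − 1) % of the cycle, so sample units and % gait cycle coincide
numerically and the cycle boundaries are samples 1 and 101. Angles are in
degrees with hip flexion, knee flexion and ankle dorsiflexion positive.
Angular velocity and acceleration are per-%-gait-cycle quantities, i.e.
derivatives with respect to normalised (not wall-clock) time. Walking
speed always enters the model as the Froude-based dimensionless speed
v* = v / √(g·L); g defaults to 9.81 m/s² and is configurable, L is the
subject's leg length in metres and is an input (marker-based estimation
is upstream of this package).

## Key-point discretisation

Each joint's waveform is reduced to an ordered set of key-points defined
relative to gait events (ipsilateral/contralateral foot strike and foot
off): either the angle at an event (or a fractional position between two
events) or an extremum searched in an event-bounded window. The built-in
sets carry 6 hip, 8 knee and 7 ankle key-points (ids HIS1–6, KNS1–8,
ANS1–7) matching the bundled coefficient table.

Numerical choices, where the procedure is under-determined:

- Fractional anchors are linearly interpolated between event timings and
  rounded half-up to the nearest sample; windows are inclusive at both
  ends.
- Extremum ties break to the first occurrence, which is deterministic and
  stable under reordering of equal values.
- Velocity/acceleration at key-points come from central finite
  differences with periodic wrap (the 100-sample period identifies sample
  101 with sample 1), consistent with the cycle-continuity constraint.
- The cycle-end key-point copies the cycle-start angle and derivatives so
  that consecutive cycles join without discontinuity.
- The hip swing-phase maximum (HIS5) is searched in the window from one
  quarter to three quarters of swing: its definition lists two fractional
  anchors, which we read as window bounds.

## Quintic reconstruction

Between consecutive key-points the curve is the unique 5th-degree
polynomial matching angle, velocity and acceleration at both ends. Each
segment is solved in a local coordinate u = (t − t₀)/h ∈ [0, 1] for
conditioning (endpoint derivatives rescaled by h, h²), using the
closed-form quintic Hermite coefficients; the test suite checks them
against a brute-force 6×6 linear solve. Matching all three quantities at
every interior knot makes the assembled curve C²-continuous, and the
duplicated boundary state makes it periodic. Knot timings may be
non-integer (regression outputs are continuous); evaluation resamples
onto the integer 1..101 grid.

The published table models timing and angle only (velocity/acceleration
equations exist as supplementary material whose values are not
reproduced here), so before reconstruction the missing derivatives are
estimated from a periodic cubic spline through the predicted
(timing, angle) pairs; a quintic segment whose six constraints come from
a cubic *is* that cubic, so the default reconstruction is effectively a
periodic cubic spline through the key-points. User-supplied derivative
coefficient tables take precedence when present.

A consequence worth knowing: discretise → reconstruct → discretise is an
exact round trip only for states on the integer grid whose extremum
key-points are genuine local extrema of the rebuilt curve. For
model-predicted states with continuous timings the re-extracted extremum
can shift (the interpolant's extremum need not sit on the knot),
especially in flat regions such as the ankle loading-response minimum.
Tests therefore assert the exact identity on grid-aligned fixtures and a
bounded deviation otherwise.

## Regression

One equation is fitted per (key-point, parameter) over a trial database;
every provided trial row is one observation. Cycle-boundary timings are
structural constants (1 and 101) and are emitted as constant records, not
fitted.

- **Stepwise selection.** Forward–backward on partial t-test p-values
  starting from the intercept-only model, entry and removal thresholds
  both α = 0.01 (the removal threshold is not separately specified
  upstream, so the stated α is applied symmetrically). Forward steps add
  the candidate with the smallest p-value, ties broken by the canonical
  speed → age → sex → BMI scan order. p-values come from statsmodels OLS.
  When a model fits the data exactly to machine precision, t-statistics
  on the leftover rounding noise are meaningless; a predictor then counts
  as significant only if its effect exceeds the numeric noise floor
  (10⁻⁸ relative to the response scale). This makes noiseless synthetic
  data recover exactly the generating sparsity pattern.
- **Robust fit.** IRLS with Tukey bisquare weights, tuning constant
  4.685 and residual scale MAD/0.6745 re-estimated each iteration
  (standard defaults of the robust-regression routine family);
  convergence when the largest coefficient update drops below 1e-8, cap
  100 iterations (non-convergence returns the last iterate with a flag).
  A collapsed scale (exactly fitting data) short-circuits to ordinary
  least squares with unit weights. The implementation is cross-checked
  against statsmodels RLM in the tests.
- **Per-equation RMSE** is the root mean square residual of the robust
  fit, in the parameter's units.
- The intercept is always present and never subject to selection;
  non-retained predictors are exactly absent from prediction, not
  zero-valued placeholders.

## Normative prediction and contributions

Evaluating the table at P yields key-point states per joint. Predicted
timings are clamped to [1, 101] and ordering-repaired (forward/backward
passes enforcing a 1-sample minimum separation) with a warning — at
extreme predictor values extrapolated timing equations can invert
neighbours. Predictions with v* outside [0.2, 0.7] are allowed but raise
an `ExtrapolationWarning`: below ≈0.2 walking degenerates into a
succession of postures and above ≈0.7 the walk–run transition begins, so
the linear model's validity degrades.

Predictor sweeps use 15 evenly spaced values over the predictor's range
(2 for the binary sex) with the other predictors at database medians.
The bundled defaults are v* = 0.45, age 38, sex 1 (the study-population
majority, 30/54 male) and BMI 24; the source database's exact medians are
not tabulated, so these are configurable. Because prediction is linear in
each predictor, a sweep's span equals |coefficient| × range width
exactly, which is how contribution ranges are computed. Clinical
significance uses a 3 % gait-cycle timing threshold (a 4-frame
event-detection window at 120 Hz over a 1.10 s cycle) and 2°/5° angle
bands (below 2° no consequence, 2–5° consider, above 5° may mislead).

## Validation

Leave-one-out holds out one *subject* at a time (all their trials),
refits on the rest and scores the held-out waveforms with RMSE (deg),
squared Pearson correlation R², and VAF = 100·(1 − var(y − ŷ)/var(y))
using population variances — VAF definitions vary; this offset-
insensitive form is the one implemented and tested. Summaries are binned
by dimensionless speed with bin width 0.05.

## Synthetic data generator

The generator emulates the reference database: n = 54 adults, sex ~
Bernoulli(30/54 male), age from a normal (SD 13.7) truncated to [19, 67]
whose location is calibrated so the post-truncation mean is 37.9 years
(naive truncation of an asymmetric range would inflate the mean by
~1.7 y), height ~ N(1.74, 0.10) m, BMI truncated-normal (mean 24, SD 3)
on [17, 31] kg/m², mass derived from BMI and height. Leg length is
0.53·height with 1 % lognormal-free jitter — a standard anthropometric
ratio, as the source database does not report leg lengths. Five speed
conditions per subject: C1–C3 uniform in the imposed 0–0.4, 0.4–0.8 and
0.8–1.2 m/s bands; C4 (spontaneous) ~ N(1.3, 0.15) and C5 (maximal) ~
N(1.9, 0.2) m/s — stand-ins chosen once from adult norms, since the
study's self-selected speed distributions are not printed.

Trials invert the prediction model: key-point timing/angle = generating
equation value + N(0, noise_scale × equation RMSE), so `noise_scale = 1`
reproduces the reported residual spread at the level where the
regression's assumptions hold exactly, and `noise_scale = 0` gives exact
ground truth for parameter-recovery tests. The cycle-end key-point copies
the cycle-start draw; timings are ordering-repaired; waveforms are
rebuilt through the same quintic pipeline. Optional smooth waveform-level
noise (a random Fourier series over harmonics 1–6 of the cycle,
configurable SD) stresses the discretisation stage with within-cycle
detail the key-points cannot represent. Gait events derive from the
foot-off timing equation with contralateral events placed by half-cycle
symmetry. Randomness is fully deterministic under the configured seed
with independent streams per (subject, condition, trial).

What passing tests on these data do **not** show: the generator contains
no soft-tissue artefact, no marker misplacement, no left/right asymmetry,
no metronome entrainment and no non-linearity outside the model family —
real-data residual structure (notably the error growth below v* ≈ 0.2
and above ≈ 0.7) cannot be reproduced without the deposited recordings.
Parameter-recovery and cross-validation results on synthetic data
establish correctness of the pipeline, not clinical validity.

## Problem sizes used in the checks

The acceptance script refits on a noiseless 54-subject × 5-condition
database (270 trials, the study design with one trial per condition,
since noiseless repeats are redundant) and evaluates the reconstruction
bound on 50 cycles with 1° smooth waveform noise; the test suite uses
10–30 subjects for fitting/validation checks, which is where the
demographic design (subject-level predictors) becomes well identified.

## Known limitations

- Sagittal plane only; timing/angle equations only by default.
- Event detection, marker processing and inverse kinematics are out of
  scope; events and waveforms are inputs.
- Stepwise selection inherits its known instability at small n: with few
  subjects the subject-level predictors are weakly identified and proxy
  models can be selected. The robust fit mitigates, not removes, the
  effect of order-repair clamping at extreme extrapolations.
- The exact medians, speed distributions and velocity/acceleration
  regressors of the source database are not available; the corresponding
  defaults are documented stand-ins.
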