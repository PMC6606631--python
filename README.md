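# gaitnorm

Virtual normative sagittal gait kinematics from walking speed, age, sex
and BMI.

## The problem

Clinical gait analysis (CGA) quantifies a patient's deviation from normal
gait by comparing their joint-angle curves against a normative database.
But normative data are usually recorded at the spontaneous walking speed
of healthy adults, while many patients walk far slower — and walking
speed, age, sex and body mass index all reshape the curves. A mismatch in
any of these can masquerade as pathology (a slow walker's reduced swing
knee flexion looks like stiff-knee gait). Instead of collecting a new
database for every patient profile, `gaitnorm` predicts a *virtual*
normative profile matched to the patient.

## The model

Each hip/knee/ankle flexion-extension waveform (101 samples over a gait
cycle) is discretised into 6 / 8 / 7 clinically meaningful **key-points**
(extrema within gait-event windows, or values at events). Each key-point
parameter — its timing *tᵢ* (1..101 sample scale) and angle *θᵢ* (deg) —
is modelled as a multilinear function of the predictor vector

```
P = [v*, age, sex, BMI]ᵀ,    X = B P
```

where *v\** = v / √(g·L) is the Froude-based dimensionless walking speed
(L = leg length), sex is coded 0 = female / 1 = male, and age/BMI are in
raw units. Predictors are screened per equation by forward–backward
stepwise selection (entry/removal p < 0.01) and the retained design is
fitted by robust IRLS with Tukey bisquare weights (c = 4.685, scale
MAD/0.6745). Continuous waveforms are rebuilt from predicted key-points
by piecewise quintic (5th-order Hermite) interpolation matching angle,
angular velocity and acceleration at every knot, with the cycle-end state
pinned to the cycle-start state so cycles chain C²-continuously.

The package bundles the published timing/angle coefficient table for all
21 key-points and provides:

- `discretise` / `reconstruct` — key-point extraction and quintic rebuild,
- `regress` — stepwise + robust fitting of a trial database,
- `normative` — patient-matched prediction, predictor sweeps, clinical
  significance labels (3 % gait-cycle timing shift; 2°/5° angle bands),
- `validate` — leave-one-subject-out cross validation (RMSE, R², VAF),
- `synth` — a synthetic study-population generator (54 adults, five speed
  conditions) with known ground truth for end-to-end testing,
- a thin `gaitnorm` CLI (`synth`, `fit`, `predict`, `reconstruct`,
  `loocv`, `contrib`, `study-keypoints`).

## Worked example

```python
import gaitnorm as gn

subject = gn.Subject(id="patient", age=40, sex=0, bmi=24.0, leg_length=0.90)
predictors = gn.encode_predictors(subject, v=1.25)   # v* = 0.4207

table = gn.load_published_table()
keypoints = gn.predict_keypoints(table, predictors)
waveforms = gn.predict_waveforms(table, predictors)
```

Running `python examples/predict_reference_gait.py` prints (excerpt):

```
dimensionless walking speed v* = 0.4207

knee: predicted range [-1.8, +54.7] deg
  KNS1:   0.0 % GC,  -1.48 deg
  KNS2:  12.9 % GC, +11.76 deg
  KNS3:  37.4 % GC,  +0.93 deg
  KNS4:  48.1 % GC,  +5.42 deg
  KNS5:  63.3 % GC, +36.33 deg
  KNS6:  72.9 % GC, +54.74 deg
  KNS7:  90.9 % GC,  +6.64 deg
  KNS8: 100.0 % GC,  -1.48 deg
```

KNS2 is the loading-response knee flexion peak (11.8° at 13 % of the
cycle for this 40-year-old woman at 1.25 m/s), KNS6 the swing-phase peak
(54.7°); the 101-sample waveforms interpolate these key-points and can be
overlaid on the patient's measured curves as a speed- and
demographics-matched reference. The other examples show predictor
contribution analysis (`predictor_contributions.py`), fitting plus
cross-validation on synthetic data (`fit_and_validate_synthetic.py`) and
the key-point-count trade-off (`keypoint_discretisation.py`).

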