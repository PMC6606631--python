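"""Predict a patient-matched normative gait profile.

A clinician has a patient walking at 1.25 m/s: rather than comparing
against norms recorded at a different (usually faster) speed, we predict
reference hip/knee/ankle sagittal kinematics matched to the patient's
speed, age, sex and BMI.
"""

import gaitnorm as gn

subject = gn.Subject(id="patient", age=40, sex=0, bmi=24.0, leg_length=0.90)
predictors = gn.encode_predictors(subject, v=1.25)
print(f"dimensionless walking speed v* = {predictors.v_star:.4f}")

table = gn.load_published_table()
keypoints = gn.predict_keypoints(table, predictors)
waveforms = gn.predict_waveforms(table, predictors)

for joint in gn.JOINTS:
    wf = waveforms[joint]
    print(f"\n{joint}: predicted range [{wf.values.min():+.1f}, {wf.values.max():+.1f}] deg")
    for s in keypoints[joint]:
        print(f"  {s.keypoint_id}: {s.timing_percent:5.1f} % GC, {s.angle:+6.2f} deg")

# The key-points are the clinical landmarks (e.g. KNS6 is the swing-phase
# knee flexion peak); the 101-sample waveforms interpolate them with
# piecewise quintics and can be overlaid on the patient's measured curves.
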