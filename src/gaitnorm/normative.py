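"""Virtual normative gait prediction and predictor-contribution analysis.

Evaluating a coefficient table at a patient's predictor vector yields the
key-point states of a reference (asymptomatic) gait pattern matched to
that patient's walking speed, age, sex and BMI; piecewise quintic
interpolation then turns the key-points into full hip/knee/ankle
waveforms.  Sweeping a single predictor over its population range, with
the others held at database medians, quantifies how much of an apparent
gait deviation a predictor mismatch alone can produce, classified against
clinical-significance thresholds (3 % of gait cycle for timing; 2 and 5
degrees for angles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import JOINTS, N_SAMPLES, GaitWaveform, KeyPointState, PredictorVector
from .discretise import builtin_schema
from .reconstruct import reconstruct_waveform
from .regress import CoefficientTable, PREDICTORS, joint_of

__all__ = [
    "ExtrapolationWarning",
    "OrderRepairWarning",
    "ContributionReport",
    "load_published_table",
    "predict_keypoints",
    "predict_waveforms",
    "complete_derivatives",
    "repair_timing_order",
    "sweep_predictor",
    "contribution_range",
    "contribution_report",
    "classify_clinical",
    "clinical_timing_threshold",
    "DEFAULT_MEDIANS",
    "DEFAULT_RANGES",
]


class ExtrapolationWarning(UserWarning):
    """Prediction outside the calibrated dimensionless-speed envelope."""


class OrderRepairWarning(UserWarning):
    """Predicted key-point timings had to be re-ordered."""


#: Default predictor medians used for sweeps when no database is attached.
#: Sex 1 is the study-population majority (30/54 male); the remaining values
#: approximate the study medians, which are not tabulated.
DEFAULT_MEDIANS: Dict[str, float] = {"speed": 0.45, "age": 38.0, "sex": 1, "bmi": 24.0}

#: Default sweep ranges: age and BMI span the study population; speed spans
#: the calibrated envelope between the very-slow-gait and walk-run
#: transition thresholds.
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "speed": (0.2, 0.7),
    "age": (19.0, 67.0),
    "sex": (0.0, 1.0),
    "bmi": (17.0, 31.0),
}

#: Calibrated dimensionless-speed envelope; outside it predictions are
#: extrapolations and validity degrades.
SPEED_ENVELOPE = (0.2, 0.7)

#: Clinically significant temporal shift, % gait cycle.
TIMING_THRESHOLD_PCT = 3.0

#: Angle bands (deg): below the first no consequence expected; between the
#: two, consideration needed; above the second, interpretation may mislead.
ANGLE_THRESHOLDS_DEG = (2.0, 5.0)


def load_published_table() -> CoefficientTable:
    """The coefficient table bundled with the package (timing + angle
    equations for all 21 key-points, with non-significant predictors
    absent and per-equation RMSE)."""
    from .io import read_coefficient_table

    path = resources.files("gaitnorm").joinpath("data/published_coefficients.csv")
    with resources.as_file(path) as p:
        table = read_coefficient_table(p)
    table.source = "published"
    return table


def repair_timing_order(
    states: Sequence[KeyPointState], min_separation: float = 1.0
) -> list[KeyPointState]:
    """Enforce schema ordering of key-point timings with a minimum gap.

    Regression equations evaluated at extreme predictor values can invert
    neighbouring timings; interior timings are clamped into [1, 101] and
    pushed apart by at least ``min_separation`` samples (forward then
    backward pass).  Emits :class:`OrderRepairWarning` when anything moved.
    """
    t = np.array([s.timing for s in states], dtype=float)
    orig = t.copy()
    t[1:-1] = np.clip(t[1:-1], 1.0 + min_separation, float(N_SAMPLES) - min_separation)
    for i in range(1, len(t) - 1):
        t[i] = max(t[i], t[i - 1] + min_separation)
    for i in range(len(t) - 2, 0, -1):
        t[i] = min(t[i], t[i + 1] - min_separation)
    if np.any(np.abs(t - orig) > 1e-12):
        moved = [s.keypoint_id for s, a, b in zip(states, orig, t) if abs(a - b) > 1e-12]
        warnings.warn(
            f"re-ordered predicted key-point timings for {moved}",
            OrderRepairWarning,
            stacklevel=2,
        )
    return [
        KeyPointState(s.keypoint_id, float(ti), s.angle, s.velocity, s.acceleration)
        for s, ti in zip(states, t)
    ]


def predict_keypoints(
    table: CoefficientTable,
    p: PredictorVector,
    joints: Sequence[str] = JOINTS,
    repair: bool = True,
) -> Dict[str, list[KeyPointState]]:
    """Evaluate every key-point equation of the requested joints at ``p``.

    Returns per-joint key-point states in schema order; timings are
    ordering-repaired.  Predictions outside the calibrated speed envelope
    are allowed but flagged with :class:`ExtrapolationWarning`.
    """
    lo, hi = SPEED_ENVELOPE
    if not lo <= p.v_star <= hi:
        warnings.warn(
            f"dimensionless speed {p.v_star:.3f} outside the calibrated "
            f"envelope [{lo}, {hi}]; prediction is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out: Dict[str, list[KeyPointState]] = {}
    for joint in joints:
        states = []
        for kp_id in builtin_schema(joint).ids:
            timing = table.get(kp_id, "timing").predict(p)
            angle = table.get(kp_id, "angle").predict(p)
            vel = (
                table.get(kp_id, "velocity").predict(p)
                if table.has(kp_id, "velocity")
                else None
            )
            acc = (
                table.get(kp_id, "acceleration").predict(p)
                if table.has(kp_id, "acceleration")
                else None
            )
            timing = float(np.clip(timing, 1.0, float(N_SAMPLES)))
            states.append(KeyPointState(kp_id, timing, angle, vel, acc))
        if repair:
            states = repair_timing_order(states)
        out[joint] = states
    return out


def complete_derivatives(
    states: Sequence[KeyPointState], angle_tol: float = 1e-6
) -> list[KeyPointState]:
    """Fill missing key-point derivatives from a periodic cubic spline.

    The published table carries no velocity/acceleration equations, so the
    derivatives needed by the quintic reconstruction are estimated from a
    periodic cubic spline through the predicted (timing, angle) pairs.
    States that already carry derivatives are left untouched.
    """
    t = np.array([s.timing for s in states], dtype=float)
    y = np.array([s.angle for s in states], dtype=float)
    if abs(y[-1] - y[0]) > angle_tol:
        raise ValueError(
            "cycle-end angle must equal cycle-start angle for a periodic "
            f"spline (difference {y[-1] - y[0]:.3g})"
        )
    y = y.copy()
    y[-1] = y[0]
    spline = CubicSpline(t, y, bc_type="periodic")
    d1 = spline(t, 1)
    d2 = spline(t, 2)
    out = []
    for s, v, a in zip(states, d1, d2):
        if s.has_derivatives:
            out.append(s)
        else:
            out.append(
                KeyPointState(s.keypoint_id, s.timing, s.angle, float(v), float(a))
            )
    return out


def predict_waveforms(
    table: CoefficientTable,
    p: PredictorVector,
    joints: Sequence[str] = JOINTS,
    side: str = "right",
) -> Dict[str, GaitWaveform]:
    """Full virtual normative waveforms at a patient's predictor vector."""
    keypoints = predict_keypoints(table, p, joints=joints)
    out = {}
    for joint, states in keypoints.items():
        states = complete_derivatives(states)
        out[joint] = reconstruct_waveform(states, joint=joint, side=side)
    return out


def _resolve_sweep(
    which: str,
    n: int,
    value_range: Optional[Tuple[float, float]],
) -> np.ndarray:
    if which not in PREDICTORS:
        raise ValueError(f"unknown predictor {which!r}; expected one of {PREDICTORS}")
    if which == "sex":
        return np.array([0.0, 1.0])
    lo, hi = value_range if value_range is not None else DEFAULT_RANGES[which]
    if not hi > lo:
        raise ValueError(f"degenerate sweep range [{lo}, {hi}] for {which!r}")
    return np.linspace(lo, hi, n)


def sweep_predictor(
    table: CoefficientTable,
    which: str,
    n: int = 15,
    value_range: Optional[Tuple[float, float]] = None,
    others: Optional[Mapping[str, float]] = None,
    joints: Sequence[str] = JOINTS,
) -> list[Tuple[float, Dict[str, list[KeyPointState]]]]:
    """Predict key-points over ``n`` evenly spaced values of one predictor.

    The other predictors sit at their database medians (two values only
    for sex, which is binary).  Returns ``(value, per-joint states)``
    pairs.
    """
    values = _resolve_sweep(which, n, value_range)
    base = dict(DEFAULT_MEDIANS)
    if others:
        base.update(others)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        for v in values:
            base_v = dict(base)
            base_v[which] = v
            p = PredictorVector(
                v_star=base_v["speed"],
                age=base_v["age"],
                sex=int(round(base_v["sex"])),
                bmi=base_v["bmi"],
            )
            out.append((float(v), predict_keypoints(table, p, joints=joints)))
    return out


def contribution_range(
    table: CoefficientTable,
    which: str,
    joint: str,
    keypoint_ids: Sequence[str],
    value_range: Optional[Tuple[float, float]] = None,
) -> Dict[str, float]:
    """Largest timing/angle change a predictor can produce over its range.

    Predictions are linear in each predictor, so the span of a sweep is
    exactly |coefficient| x range width (the coefficient itself for the
    binary sex predictor); non-significant predictors contribute zero.
    Returns the maximum over the listed key-points per parameter.
    """
    values = _resolve_sweep(which, 2, value_range)
    width = float(values[-1] - values[0])
    out = {"timing": 0.0, "angle": 0.0}
    for kp_id in keypoint_ids:
        if joint_of(kp_id) != joint:
            raise ValueError(f"key-point {kp_id!r} does not belong to joint {joint!r}")
        for param in ("timing", "angle"):
            rec = table.get(kp_id, param)
            beta = rec.coefficients.get(which, 0.0)
            out[param] = max(out[param], abs(beta) * width)
    return out


def classify_clinical(
    delta_timing: float, delta_angle: float
) -> Tuple[str, str]:
    """Clinical-significance labels for a timing shift and an angle change.

    Timing (in % gait cycle) is significant beyond 3 % of the cycle (a
    4-frame event-detection window at 120 Hz over a 1.10 s cycle); angles
    follow the 2/5 degree bands: below 2 no consequence, 2-5 needs
    consideration, above 5 interpretation may mislead.
    """
    if delta_timing < 0 or delta_angle < 0:
        raise ValueError("clinical deltas must be non-negative")
    timing_label = (
        "significant" if delta_timing > TIMING_THRESHOLD_PCT else "not_significant"
    )
    low, high = ANGLE_THRESHOLDS_DEG
    if delta_angle < low:
        angle_label = "none"
    elif delta_angle <= high:
        angle_label = "consider"
    else:
        angle_label = "may_mislead"
    return timing_label, angle_label


def clinical_timing_threshold(
    n_frames: int = 4,
    capture_rate_hz: float = 120.0,
    cycle_duration_s: float = 1.10,
) -> float:
    """Timing threshold in % gait cycle from an event-detection window.

    A ``n_frames`` window at ``capture_rate_hz`` (the benchmark accuracy of
    automated gait-event detection) expressed as a fraction of the average
    gait cycle duration, rounded to the nearest percent.
    """
    if n_frames <= 0 or capture_rate_hz <= 0 or cycle_duration_s <= 0:
        raise ValueError("window parameters must be positive")
    pct = 100.0 * (n_frames / capture_rate_hz) / cycle_duration_s
    return float(round(pct))


@dataclass(frozen=True)
class ContributionReport:
    """Per-key-point contribution of one predictor across its sweep."""

    predictor: str
    values: Tuple[float, ...]
    frame: pd.DataFrame  # joint, keypoint_id, deltas, clinical labels


def contribution_report(
    table: CoefficientTable,
    which: str,
    value_range: Optional[Tuple[float, float]] = None,
    joints: Sequence[str] = JOINTS,
    n: int = 15,
) -> ContributionReport:
    """Contribution of one predictor at every key-point, with labels."""
    values = _resolve_sweep(which, n, value_range)
    width = float(values[-1] - values[0])
    rows = []
    for joint in joints:
        for kp_id in builtin_schema(joint).ids:
            deltas = {}
            for param in ("timing", "angle"):
                beta = table.get(kp_id, param).coefficients.get(which, 0.0)
                deltas[param] = abs(beta) * width
            timing_label, angle_label = classify_clinical(
                deltas["timing"], deltas["angle"]
            )
            rows.append(
                {
                    "joint": joint,
                    "keypoint_id": kp_id,
                    "delta_timing_pct": deltas["timing"],
                    "delta_angle_deg": deltas["angle"],
                    "timing_label": timing_label,
                    "angle_label": angle_label,
                }
            )
    return ContributionReport(
        predictor=which,
        values=tuple(float(v) for v in values),
        frame=pd.DataFrame(rows),
    )
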