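"""Core domain types for gait-cycle kinematics and predictor encoding.

A gait cycle runs from one foot strike of a limb to the next strike of the
same limb and is time-normalised to 101 samples: sample ``k`` on the 1..101
scale corresponds to ``(k - 1)`` % of the gait cycle.  Joint angles are in
degrees with flexion (hip, knee) and dorsiflexion (ankle) positive.

Walking speed enters every regression as the Froude-based dimensionless
speed ``v* = v / sqrt(g * leg_length)``, which removes stature effects; the
walk-to-run transition sits near ``v* = 0.7``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "JOINTS",
    "N_SAMPLES",
    "GaitWaveform",
    "GaitEvents",
    "Subject",
    "PredictorVector",
    "KeyPointState",
    "dimensionless_speed",
    "encode_predictors",
]

#: Joints modelled, in anatomical proximal-to-distal order.
JOINTS = ("hip", "knee", "ankle")

#: Samples per time-normalised gait cycle (0..100 % in 1 % steps).
N_SAMPLES = 101

#: Standard gravitational acceleration, m/s^2.
GRAVITY = 9.81

SIDES = ("left", "right")


def _check_joint(joint: str) -> str:
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    return joint


@dataclass(frozen=True)
class GaitWaveform:
    """One joint's sagittal angle trace over a normalised gait cycle.

    Parameters
    ----------
    joint : {"hip", "knee", "ankle"}
    values : array-like of shape (101,)
        Angles in degrees, sample ``k`` at ``(k - 1)`` % gait cycle.
    side : {"left", "right"}
    """

    joint: str
    values: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        _check_joint(self.joint)
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_SAMPLES,):
            raise ValueError(
                f"waveform must have exactly {N_SAMPLES} samples, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("waveform contains non-finite samples")
        object.__setattr__(self, "values", vals)

    @property
    def percent_grid(self) -> np.ndarray:
        """Percent-of-gait-cycle axis (0..100)."""
        return np.arange(N_SAMPLES, dtype=float)


@dataclass(frozen=True)
class GaitEvents:
    """Gait-event timings in % gait cycle for one analysed cycle.

    The ipsilateral foot strike opens the cycle at 0 % and the next
    ipsilateral foot strike closes it at 100 %; the three interior events
    must be strictly ordered between them.
    """

    contralateral_foot_off: float
    contralateral_foot_strike: float
    ipsilateral_foot_off: float

    ipsilateral_foot_strike: float = field(default=0.0, init=False)
    next_ipsilateral_foot_strike: float = field(default=100.0, init=False)

    def __post_init__(self) -> None:
        seq = (
            0.0,
            self.contralateral_foot_off,
            self.contralateral_foot_strike,
            self.ipsilateral_foot_off,
            100.0,
        )
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(
                "gait events must satisfy 0 < contralateral foot off < "
                f"contralateral foot strike < ipsilateral foot off < 100, got {seq}"
            )

    def percent(self, name: str) -> float:
        """Timing of event ``name`` in % gait cycle."""
        try:
            return float(getattr(self, name))
        except AttributeError:
            raise KeyError(f"unknown gait event {name!r}") from None


@dataclass(frozen=True)
class Subject:
    """Demographics and anthropometry of one participant.

    Sex is coded 0 for female and 1 for male; BMI in kg/m^2, leg length in
    metres (distance from anterior iliac spine to medial malleolus, an
    input here, not derived from markers).
    """

    id: str
    age: float
    sex: int
    bmi: float
    leg_length: float
    height: Optional[float] = None
    mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded 0 (female) or 1 (male)")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.bmi > 0:
            raise ValueError("BMI must be positive")
        if not self.leg_length > 0:
            raise ValueError("leg length must be positive")
        if self.height is not None and self.mass is not None:
            implied = self.mass / self.height**2
            if abs(implied - self.bmi) > 0.1:
                raise ValueError(
                    f"BMI {self.bmi:.2f} inconsistent with mass/height^2 "
                    f"= {implied:.2f} (tolerance 0.1)"
                )


@dataclass(frozen=True)
class PredictorVector:
    """Predictors of the regression model: [v*, age, sex, BMI].

    ``v_star`` is the dimensionless walking speed; age in years, sex coded
    0/1, BMI in kg/m^2.  Raw units throughout, no standardisation.
    """

    v_star: float
    age: float
    sex: int
    bmi: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("predictor vector contains non-finite values")
        if self.v_star < 0:
            raise ValueError("dimensionless speed must be non-negative")

    def as_array(self) -> np.ndarray:
        """Canonical order: speed, age, sex, BMI."""
        return np.array(
            [self.v_star, self.age, float(self.sex), self.bmi], dtype=float
        )


@dataclass(frozen=True)
class KeyPointState:
    """Timing, angle and angular derivatives of one waveform key-point.

    ``timing`` lives on the 1..101 sample scale (1 sample = 1 % gait
    cycle); ``angle`` in degrees; ``velocity`` in deg per % gait cycle and
    ``acceleration`` in deg per (% gait cycle)^2 when available.
    """

    keypoint_id: str
    timing: float
    angle: float
    velocity: Optional[float] = None
    acceleration: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1.0 <= self.timing <= 101.0:
            raise ValueError(
                f"{self.keypoint_id}: timing {self.timing} outside the 1..101 scale"
            )
        if not math.isfinite(self.angle):
            raise ValueError(f"{self.keypoint_id}: non-finite angle")

    @property
    def timing_percent(self) -> float:
        """Timing expressed in % gait cycle (0..100)."""
        return self.timing - 1.0

    @property
    def has_derivatives(self) -> bool:
        return self.velocity is not None and self.acceleration is not None


def dimensionless_speed(
    v: float, leg_length: float, g: float = GRAVITY
) -> float:
    """Froude-based dimensionless walking speed ``v / sqrt(g * L)``.

    Parameters
    ----------
    v : float
        Raw walking speed, m/s (>= 0).
    leg_length : float
        Leg length, m (> 0).
    g : float
        Gravitational acceleration, m/s^2 (> 0).
    """
    if leg_length <= 0:
        raise ValueError("leg length must be positive")
    if g <= 0:
        raise ValueError("gravitational constant must be positive")
    if v < 0:
        raise ValueError("walking speed must be non-negative")
    return v / math.sqrt(g * leg_length)


def encode_predictors(
    subject: Subject, v: float, g: float = GRAVITY
) -> PredictorVector:
    """Build the predictor vector for ``subject`` walking at ``v`` m/s."""
    return PredictorVector(
        v_star=dimensionless_speed(v, subject.leg_length, g=g),
        age=subject.age,
        sex=subject.sex,
        bmi=subject.bmi,
    )
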