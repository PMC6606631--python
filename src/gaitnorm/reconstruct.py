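"""Piecewise quintic reconstruction of waveforms from key-point states.

Between two consecutive key-points the angle trace is the unique degree-5
polynomial matching angle, angular velocity and angular acceleration at
both ends (quintic Hermite interpolation).  Matching all three quantities
at every knot makes the assembled curve C2-continuous, and because the
cycle-end state duplicates the cycle-start state the reconstruction chains
periodically across gait cycles without kinks.

Segments are solved in a local coordinate u = (t - t_left) / h in [0, 1]
for numerical conditioning; endpoint derivatives are rescaled by h and h^2
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .core import N_SAMPLES, GaitWaveform, KeyPointState

__all__ = [
    "QuinticSegment",
    "solve_quintic_segment",
    "reconstruct_waveform",
    "evaluate_piecewise",
    "waveform_rmse",
]


@dataclass(frozen=True)
class QuinticSegment:
    """One quintic piece on [t_left, t_right], coefficients in local u."""

    t_left: float
    t_right: float
    coeffs: Tuple[float, float, float, float, float, float]  # c0..c5 in u

    @property
    def h(self) -> float:
        return self.t_right - self.t_left

    def _u(self, t):
        return (np.asarray(t, dtype=float) - self.t_left) / self.h

    def __call__(self, t):
        u = self._u(t)
        c = self.coeffs
        return c[0] + u * (c[1] + u * (c[2] + u * (c[3] + u * (c[4] + u * c[5]))))

    def derivative(self, t, order: int = 1):
        """Derivative with respect to t (deg per % gait cycle units)."""
        u = self._u(t)
        c = self.coeffs
        if order == 1:
            du = c[1] + u * (2 * c[2] + u * (3 * c[3] + u * (4 * c[4] + u * 5 * c[5])))
            return du / self.h
        if order == 2:
            ddu = 2 * c[2] + u * (6 * c[3] + u * (12 * c[4] + u * 20 * c[5]))
            return ddu / self.h**2
        raise ValueError("order must be 1 or 2")


def solve_quintic_segment(
    left: KeyPointState, right: KeyPointState
) -> QuinticSegment:
    """Unique quintic matching angle/velocity/acceleration at both ends."""
    h = right.timing - left.timing
    if h <= 0:
        raise ValueError(
            f"degenerate segment: {left.keypoint_id} at {left.timing} to "
            f"{right.keypoint_id} at {right.timing}"
        )
    for s in (left, right):
        if not s.has_derivatives:
            raise ValueError(
                f"{s.keypoint_id}: velocity/acceleration required for quintic "
                "interpolation (complete derivatives first)"
            )
    p0, p1 = left.angle, right.angle
    v0, v1 = left.velocity * h, right.velocity * h
    a0, a1 = left.acceleration * h * h, right.acceleration * h * h
    d = p1 - p0
    c0 = p0
    c1 = v0
    c2 = a0 / 2.0
    c3 = 10.0 * d - 6.0 * v0 - 4.0 * v1 - 1.5 * a0 + 0.5 * a1
    c4 = -15.0 * d + 8.0 * v0 + 7.0 * v1 + 1.5 * a0 - a1
    c5 = 6.0 * d - 3.0 * (v0 + v1) - 0.5 * (a0 - a1)
    if not np.all(np.isfinite([c0, c1, c2, c3, c4, c5])):
        raise ValueError("non-finite boundary values in quintic segment")
    return QuinticSegment(
        t_left=float(left.timing),
        t_right=float(right.timing),
        coeffs=(c0, c1, c2, c3, c4, c5),
    )


def _build_segments(states: Sequence[KeyPointState]) -> list[QuinticSegment]:
    if len(states) < 2:
        raise ValueError("at least two key-point states are required")
    timings = [s.timing for s in states]
    if any(b <= a for a, b in zip(timings, timings[1:])):
        raise ValueError(
            f"key-point timings must be strictly increasing, got {timings}"
        )
    if abs(states[0].timing - 1.0) > 1e-9 or abs(states[-1].timing - N_SAMPLES) > 1e-9:
        raise ValueError(
            "states must open at sample 1 and close at sample 101 "
            f"(got {states[0].timing}..{states[-1].timing})"
        )
    return [solve_quintic_segment(a, b) for a, b in zip(states, states[1:])]


def evaluate_piecewise(
    states: Sequence[KeyPointState], t: np.ndarray
) -> np.ndarray:
    """Evaluate the piecewise quintic through ``states`` at times ``t``."""
    segments = _build_segments(states)
    t = np.asarray(t, dtype=float)
    knots = np.array([s.t_left for s in segments[1:]])
    idx = np.searchsorted(knots, t, side="right")
    out = np.empty_like(t)
    for i, seg in enumerate(segments):
        mask = idx == i
        if np.any(mask):
            out[mask] = seg(t[mask])
    return out


def reconstruct_waveform(
    states: Sequence[KeyPointState], joint: str, side: str = "right"
) -> GaitWaveform:
    """Rebuild a 101-sample waveform from ordered key-point states.

    States must be sorted with the first at sample 1 and a closing state at
    sample 101 equal to the first (cycle continuity).  Knot timings may be
    non-integer; the curve is resampled on the integer 1..101 grid.
    """
    grid = np.arange(1, N_SAMPLES + 1, dtype=float)
    values = evaluate_piecewise(states, grid)
    return GaitWaveform(joint=joint, values=values, side=side)


def waveform_rmse(a: GaitWaveform, b: GaitWaveform) -> float:
    """Root mean square difference between two waveforms, degrees."""
    if a.joint != b.joint:
        raise ValueError(f"joint mismatch: {a.joint!r} vs {b.joint!r}")
    diff = a.values - b.values
    return float(np.sqrt(np.mean(diff * diff)))
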