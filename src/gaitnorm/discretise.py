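"""Key-point discretisation of gait waveforms.

Each joint waveform is reduced to a handful of clinically meaningful
key-points: either the angle at a gait event (or at a fractional position
between two events), or an extremum searched within an event-bounded
window.  The built-in schemas carry 6 hip, 8 knee and 7 ankle key-points
whose ids (HIS*, KNS*, ANS*) match the bundled coefficient table.

Key-point timings are reported on the 1..101 sample grid.  Angular
velocity and acceleration at each key-point come from central finite
differences with periodic wrap (the cycle is treated as periodic, sample
101 being the same instant as sample 1 of the next cycle), and the
cycle-end key-point copies the cycle-start state so that reconstructed
cycles chain continuously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import JOINTS, N_SAMPLES, GaitEvents, GaitWaveform, KeyPointState

__all__ = [
    "Anchor",
    "KeyPointDef",
    "KeyPointSchema",
    "builtin_schema",
    "uniform_schema",
    "resolve_anchor",
    "resolve_window",
    "extract_keypoints",
    "cycle_derivatives",
    "discretisation_study",
]

ANGLE_AT = "angle_at_event"
MIN_IN = "min_in_window"
MAX_IN = "max_in_window"

_EVENT_NAMES = (
    "ipsilateral_foot_strike",
    "contralateral_foot_off",
    "contralateral_foot_strike",
    "ipsilateral_foot_off",
    "next_ipsilateral_foot_strike",
)


@dataclass(frozen=True)
class Anchor:
    """A temporal anchor: a gait event, or a fraction of the way between two.

    ``Anchor("ipsilateral_foot_off")`` is the event itself;
    ``Anchor("ipsilateral_foot_off", "next_ipsilateral_foot_strike", 0.75)``
    is three quarters of the way from foot off to the next foot strike.
    """

    event: str
    event2: Optional[str] = None
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.event not in _EVENT_NAMES:
            raise ValueError(f"unknown gait event {self.event!r}")
        if self.event2 is not None and self.event2 not in _EVENT_NAMES:
            raise ValueError(f"unknown gait event {self.event2!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("anchor fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        if self.event2 is None:
            return {"event": self.event}
        return {
            "between": [self.event, self.event2],
            "fraction": self.fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Anchor":
        if "event" in d:
            return cls(d["event"])
        e1, e2 = d["between"]
        return cls(e1, e2, float(d["fraction"]))


@dataclass(frozen=True)
class KeyPointDef:
    """Definition of one key-point: what to take, and where to look."""

    id: str
    item: str  # ANGLE_AT | MIN_IN | MAX_IN
    start: Anchor
    end: Optional[Anchor] = None

    def __post_init__(self) -> None:
        if self.item not in (ANGLE_AT, MIN_IN, MAX_IN):
            raise ValueError(f"unknown key-point item {self.item!r}")
        if self.item == ANGLE_AT and self.end is not None:
            raise ValueError(f"{self.id}: instantaneous key-point takes one anchor")
        if self.item != ANGLE_AT and self.end is None:
            raise ValueError(f"{self.id}: window key-point needs two anchors")


@dataclass(frozen=True)
class KeyPointSchema:
    """Ordered key-point definitions for one joint."""

    joint: str
    defs: Tuple[KeyPointDef, ...]

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        object.__setattr__(self, "defs", tuple(self.defs))

    def __len__(self) -> int:
        return len(self.defs)

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(d.id for d in self.defs)

    def to_json(self) -> str:
        payload = {
            "joint": self.joint,
            "defs": [
                {
                    "id": d.id,
                    "item": d.item,
                    "at_from": d.start.to_dict(),
                    "to": None if d.end is None else d.end.to_dict(),
                }
                for d in self.defs
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "KeyPointSchema":
        payload = json.loads(text)
        defs = tuple(
            KeyPointDef(
                id=d["id"],
                item=d["item"],
                start=Anchor.from_dict(d["at_from"]),
                end=None if d["to"] is None else Anchor.from_dict(d["to"]),
            )
            for d in payload["defs"]
        )
        return cls(joint=payload["joint"], defs=defs)


def _a(event: str) -> Anchor:
    return Anchor(event)


def _frac(e1: str, e2: str, f: float) -> Anchor:
    return Anchor(e1, e2, f)


_IFS = "ipsilateral_foot_strike"
_CFO = "contralateral_foot_off"
_CFS = "contralateral_foot_strike"
_IFO = "ipsilateral_foot_off"
_NFS = "next_ipsilateral_foot_strike"

_BUILTIN = {
    "hip": (
        KeyPointDef("HIS1", ANGLE_AT, _a(_IFS)),
        KeyPointDef("HIS2", ANGLE_AT, _frac(_IFS, _IFO, 0.5)),
        KeyPointDef("HIS3", MIN_IN, _a(_IFS), _a(_IFO)),
        KeyPointDef("HIS4", ANGLE_AT, _a(_IFO)),
        KeyPointDef("HIS5", MAX_IN, _frac(_IFO, _NFS, 0.25), _frac(_IFO, _NFS, 0.75)),
        KeyPointDef("HIS6", ANGLE_AT, _a(_NFS)),
    ),
    "knee": (
        KeyPointDef("KNS1", ANGLE_AT, _a(_IFS)),
        KeyPointDef("KNS2", MAX_IN, _a(_IFS), _frac(_IFS, _IFO, 0.5)),
        KeyPointDef("KNS3", MIN_IN, _frac(_IFS, _IFO, 0.5), _a(_IFO)),
        KeyPointDef("KNS4", ANGLE_AT, _frac(_IFS, _IFO, 0.75)),
        KeyPointDef("KNS5", ANGLE_AT, _a(_IFO)),
        KeyPointDef("KNS6", MAX_IN, _a(_IFO), _a(_NFS)),
        KeyPointDef("KNS7", ANGLE_AT, _frac(_IFO, _NFS, 0.75)),
        KeyPointDef("KNS8", ANGLE_AT, _a(_NFS)),
    ),
    "ankle": (
        KeyPointDef("ANS1", ANGLE_AT, _a(_IFS)),
        KeyPointDef("ANS2", MIN_IN, _a(_IFS), _a(_CFO)),
        KeyPointDef("ANS3", ANGLE_AT, _frac(_IFS, _IFO, 0.5)),
        KeyPointDef("ANS4", MAX_IN, _a(_IFS), _a(_IFO)),
        KeyPointDef("ANS5", MIN_IN, _a(_CFS), _frac(_IFO, _NFS, 0.5)),
        KeyPointDef("ANS6", MAX_IN, _a(_IFO), _frac(_IFO, _NFS, 0.75)),
        KeyPointDef("ANS7", ANGLE_AT, _a(_NFS)),
    ),
}


def builtin_schema(joint: str) -> KeyPointSchema:
    """Built-in key-point schema for ``joint`` (hip: 6, knee: 8, ankle: 7)."""
    if joint not in _BUILTIN:
        raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    return KeyPointSchema(joint=joint, defs=_BUILTIN[joint])


def uniform_schema(joint: str, n: int) -> KeyPointSchema:
    """Schema of ``n`` evenly spaced instantaneous key-points over the cycle.

    Used by the key-point-count study: with ``n = 101`` every sample is a
    key-point and reconstruction is exact.
    """
    if n < 2:
        raise ValueError("uniform schema needs at least 2 key-points")
    defs = []
    for i in range(n):
        f = i / (n - 1)
        if i == 0:
            anchor = _a(_IFS)
        elif i == n - 1:
            anchor = _a(_NFS)
        else:
            anchor = _frac(_IFS, _NFS, f)
        defs.append(KeyPointDef(f"{joint.upper()[:2]}U{i + 1}", ANGLE_AT, anchor))
    return KeyPointSchema(joint=joint, defs=tuple(defs))


def resolve_anchor(anchor: Anchor, events: GaitEvents) -> int:
    """Map an anchor to the nearest sample on the 1..101 grid (half-up)."""
    p1 = events.percent(anchor.event)
    if anchor.event2 is None:
        pct = p1
    else:
        p2 = events.percent(anchor.event2)
        pct = p1 + anchor.fraction * (p2 - p1)
    return int(np.floor(pct + 0.5)) + 1


def resolve_window(kp: KeyPointDef, events: GaitEvents) -> Tuple[int, int]:
    """Resolve a key-point's temporal window to inclusive sample bounds."""
    start = resolve_anchor(kp.start, events)
    end = start if kp.end is None else resolve_anchor(kp.end, events)
    if start > end:
        raise ValueError(
            f"{kp.id}: resolved window [{start}, {end}] is inverted; "
            "schema and events are inconsistent"
        )
    return start, end


def cycle_derivatives(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Central-difference velocity and acceleration with periodic wrap.

    Units: deg per % gait cycle and deg per (% gait cycle)^2.  The 101-th
    sample duplicates the first, so the periodic neighbour of sample 1 is
    sample 100 and of sample 101 is sample 2.
    """
    y = np.asarray(values, dtype=float)
    # drop duplicated end sample -> one period of 100 samples
    per = y[:-1]
    left = np.roll(per, 1)
    right = np.roll(per, -1)
    vel = (right - left) / 2.0
    acc = right - 2.0 * per + left
    vel = np.append(vel, vel[0])
    acc = np.append(acc, acc[0])
    return vel, acc


def extract_keypoints(
    waveform: GaitWaveform,
    events: GaitEvents,
    schema: Optional[KeyPointSchema] = None,
) -> list[KeyPointState]:
    """Extract the schema's key-points from one waveform.

    Extrema take the first occurrence on ties; the final key-point (anchored
    at the next foot strike) copies the angle and derivatives of the first
    to enforce cycle continuity.
    """
    if schema is None:
        schema = builtin_schema(waveform.joint)
    if schema.joint != waveform.joint:
        raise ValueError(
            f"schema joint {schema.joint!r} does not match waveform {waveform.joint!r}"
        )
    y = waveform.values
    vel, acc = cycle_derivatives(y)
    states: list[KeyPointState] = []
    for kp in schema.defs:
        start, end = resolve_window(kp, events)
        if kp.item == ANGLE_AT:
            idx = start - 1
        else:
            window = y[start - 1 : end]
            offset = int(np.argmin(window) if kp.item == MIN_IN else np.argmax(window))
            idx = start - 1 + offset
        states.append(
            KeyPointState(
                keypoint_id=kp.id,
                timing=float(idx + 1),
                angle=float(y[idx]),
                velocity=float(vel[idx]),
                acceleration=float(acc[idx]),
            )
        )
    # cycle-end state := cycle-start state, placed at sample 101
    first = states[0]
    states[-1] = KeyPointState(
        keypoint_id=states[-1].keypoint_id,
        timing=float(N_SAMPLES),
        angle=first.angle,
        velocity=first.velocity,
        acceleration=first.acceleration,
    )
    return states


def discretisation_study(
    waveforms: Sequence[Tuple[GaitWaveform, GaitEvents]],
    schema_variants: Iterable[KeyPointSchema],
) -> pd.DataFrame:
    """Mean reconstruction RMSE as a function of key-point count.

    For each candidate schema, every waveform is discretised and rebuilt by
    piecewise quintic interpolation; the table reports the mean RMSE across
    waveforms per variant (mirroring the key-point-count trade-off study).
    """
    from .reconstruct import reconstruct_waveform, waveform_rmse

    variants = list(schema_variants)
    if not variants:
        raise ValueError("at least one schema variant is required")
    if not waveforms:
        raise ValueError("at least one waveform is required")
    rows = []
    for schema in variants:
        errors = []
        for wf, events in waveforms:
            if wf.joint != schema.joint:
                continue
            states = extract_keypoints(wf, events, schema)
            states = dedupe_states(states)
            rec = reconstruct_waveform(states, joint=wf.joint, side=wf.side)
            errors.append(waveform_rmse(wf, rec))
        if not errors:
            raise ValueError(
                f"no waveform matches schema joint {schema.joint!r}"
            )
        rows.append(
            {
                "joint": schema.joint,
                "n_keypoints": len(schema),
                "mean_rmse_deg": float(np.mean(errors)),
                "n_waveforms": len(errors),
            }
        )
    return pd.DataFrame(rows)


def dedupe_states(states: Sequence[KeyPointState]) -> list[KeyPointState]:
    """Drop later key-points that landed on an already-used sample.

    Window boundaries of adjacent key-points can coincide (e.g. an extremum
    sitting exactly on a shared window edge); reconstruction needs strictly
    increasing knots, so the first occurrence wins.
    """
    first, last = states[0], states[-1]
    out: list[KeyPointState] = [first]
    for s in states[1:-1]:
        if s.timing <= out[-1].timing or s.timing >= last.timing:
            continue
        out.append(s)
    out.append(last)
    return out
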