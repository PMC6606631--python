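"""File formats: coefficient tables, waveform/event files, run configs.

Native formats are plain CSV and JSON — the package operates downstream of
motion-capture processing, so marker-level formats (C3D) are out of scope.
Readers validate rather than coerce: wrong sample counts, unordered events
or non-finite values are errors that name the offending record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import N_SAMPLES, GaitEvents, GaitWaveform
from .regress import (
    CoefficientTable,
    PREDICTORS,
    RegressionRecord,
    joint_of,
)

__all__ = [
    "read_coefficient_table",
    "write_coefficient_table",
    "read_waveforms",
    "write_waveforms",
    "read_events",
    "write_events",
    "RunConfig",
    "write_manifest",
]

_NS = "NS"


def read_coefficient_table(path) -> CoefficientTable:
    """Read a coefficient table CSV (NS marks non-significant predictors).

    Layout: joint, keypoint_id, parameter, beta0, beta_speed, beta_age,
    beta_sex, beta_bmi, rmse, n_predictors, is_constant.
    """
    df = pd.read_csv(path, dtype=str).fillna(_NS)
    required = {"keypoint_id", "parameter", "beta0"}
    if not required <= set(df.columns):
        raise ValueError(f"coefficient table lacks columns {required - set(df.columns)}")
    records = []
    for _, row in df.iterrows():
        kp_id = row["keypoint_id"]
        joint_of(kp_id)  # raises on unknown ids
        if row["beta0"].strip() == _NS:
            raise ValueError(
                f"{kp_id} {row['parameter']}: intercept cannot be NS "
                "(the intercept is always present)"
            )
        coefficients = {}
        for name in PREDICTORS:
            raw = str(row.get(f"beta_{name}", _NS)).strip()
            if raw != _NS:
                try:
                    coefficients[name] = float(raw)
                except ValueError:
                    raise ValueError(
                        f"{kp_id} {row['parameter']}: malformed coefficient "
                        f"{raw!r} for {name} (use a number or NS)"
                    ) from None
        is_constant = str(row.get("is_constant", "false")).strip().lower() == "true"
        rmse_raw = str(row.get("rmse", "nan")).strip()
        rmse = float("nan") if rmse_raw == _NS else float(rmse_raw)
        records.append(
            RegressionRecord(
                keypoint_id=kp_id,
                parameter=row["parameter"].strip(),
                intercept=float(row["beta0"]),
                coefficients=coefficients,
                rmse=rmse,
                is_constant=is_constant,
            )
        )
    return CoefficientTable(records, source="file")


def write_coefficient_table(table: CoefficientTable, path) -> None:
    """Write a coefficient table CSV; round-trips through the reader."""
    rows = []
    for rec in table:
        row = {
            "joint": joint_of(rec.keypoint_id),
            "keypoint_id": rec.keypoint_id,
            "parameter": rec.parameter,
            "beta0": repr(rec.intercept),
        }
        for name in PREDICTORS:
            beta = rec.coefficients.get(name)
            row[f"beta_{name}"] = _NS if beta is None else repr(beta)
        row["rmse"] = _NS if np.isnan(rec.rmse) else repr(rec.rmse)
        row["n_predictors"] = rec.n_predictors
        row["is_constant"] = "true" if rec.is_constant else "false"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_waveforms(
    waveform_csv, events_json
) -> Dict[str, Tuple[Dict[str, GaitWaveform], GaitEvents]]:
    """Read cycles from a waveform CSV plus an events JSON.

    The CSV needs columns cycle_id, joint, side, sample (1..101) and
    angle_deg, 101 rows per (cycle, joint); the JSON maps each cycle id to
    its contralateral foot off / contralateral foot strike / ipsilateral
    foot off timings in % gait cycle.
    """
    df = pd.read_csv(waveform_csv)
    required = {"cycle_id", "joint", "side", "sample", "angle_deg"}
    if not required <= set(df.columns):
        raise ValueError(f"waveform CSV lacks columns {required - set(df.columns)}")
    events_by_cycle = read_events(events_json)
    out: Dict[str, Tuple[Dict[str, GaitWaveform], GaitEvents]] = {}
    for (cycle_id, joint), group in df.groupby(["cycle_id", "joint"], sort=False):
        cycle_id = str(cycle_id)
        if len(group) != N_SAMPLES:
            raise ValueError(
                f"cycle {cycle_id!r} joint {joint!r}: expected {N_SAMPLES} "
                f"samples, found {len(group)}"
            )
        group = group.sort_values("sample")
        if not np.array_equal(group["sample"].to_numpy(), np.arange(1, N_SAMPLES + 1)):
            raise ValueError(
                f"cycle {cycle_id!r} joint {joint!r}: sample column must "
                "run 1..101 without gaps"
            )
        side = group["side"].iloc[0]
        wf = GaitWaveform(
            joint=joint, values=group["angle_deg"].to_numpy(dtype=float), side=side
        )
        if cycle_id not in events_by_cycle:
            raise ValueError(f"no gait events for cycle {cycle_id!r}")
        joints, events = out.setdefault(cycle_id, ({}, events_by_cycle[cycle_id]))
        joints[joint] = wf
    return out


def write_waveforms(
    cycles: Dict[str, Tuple[Dict[str, GaitWaveform], GaitEvents]],
    waveform_csv,
    events_json,
) -> None:
    rows = []
    events_payload = {}
    for cycle_id, (joints, events) in cycles.items():
        events_payload[cycle_id] = {
            "contralateral_foot_off": events.contralateral_foot_off,
            "contralateral_foot_strike": events.contralateral_foot_strike,
            "ipsilateral_foot_off": events.ipsilateral_foot_off,
        }
        for joint, wf in joints.items():
            for k, angle in enumerate(wf.values, start=1):
                rows.append(
                    {
                        "cycle_id": cycle_id,
                        "joint": joint,
                        "side": wf.side,
                        "sample": k,
                        "angle_deg": angle,
                    }
                )
    pd.DataFrame(rows).to_csv(waveform_csv, index=False)
    Path(events_json).write_text(json.dumps(events_payload, indent=2))


def read_events(path) -> Dict[str, GaitEvents]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for cycle_id, ev in payload.items():
        out[str(cycle_id)] = GaitEvents(
            contralateral_foot_off=float(ev["contralateral_foot_off"]),
            contralateral_foot_strike=float(ev["contralateral_foot_strike"]),
            ipsilateral_foot_off=float(ev["ipsilateral_foot_off"]),
        )
    return out


def write_events(events: Dict[str, GaitEvents], path) -> None:
    payload = {
        cid: {
            "contralateral_foot_off": ev.contralateral_foot_off,
            "contralateral_foot_strike": ev.contralateral_foot_strike,
            "ipsilateral_foot_off": ev.ipsilateral_foot_off,
        }
        for cid, ev in events.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class RunConfig:
    """Run-level configuration; defaults reproduce the reference constants."""

    seed: int = 0
    alpha: float = 0.01
    robust_tuning: float = 4.685
    sweep_n: int = 15
    timing_threshold_pct: float = 3.0
    angle_thresholds_deg: Tuple[float, float] = (2.0, 5.0)
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "angle_thresholds_deg" in payload:
            payload["angle_thresholds_deg"] = tuple(payload["angle_thresholds_deg"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["angle_thresholds_deg"] = list(self.angle_thresholds_deg)
        return d


def write_manifest(out_dir, config: Optional[RunConfig] = None, **extra) -> Path:
    """Write a run manifest (config, seed, package version) beside outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"gaitnorm_version": __version__}
    if config is not None:
        payload["config"] = config.to_dict()
    payload.update(extra)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
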