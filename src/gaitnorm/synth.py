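"""Synthetic study populations and gait trials with known ground truth.

The generator emulates the reference database the regression equations
were built on: 54 adults (24 women / 30 men), ages 19-67 (37.9 +/- 13.7),
BMI 17-31 kg/m^2, walking at five speed conditions (three imposed bands
of 0-0.4, 0.4-0.8 and 0.8-1.2 m/s, then spontaneous and maximal
self-selected speeds), five gait trials per condition.

Trials are generated by inverting the prediction model: key-point timings
and angles come from a generating coefficient table evaluated at the
subject's predictors, plus Gaussian noise scaled by each equation's
residual RMSE (``noise_scale`` = 1 reproduces the reported residual
spread; 0 is noiseless ground truth).  Waveforms are then reconstructed
through the same quintic pipeline, optionally with smooth band-limited
waveform-level noise for reconstruction stress tests.  Everything is
deterministic under the configured seed, with independent streams per
(subject, condition, trial).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    JOINTS,
    N_SAMPLES,
    GaitEvents,
    GaitWaveform,
    KeyPointState,
    PredictorVector,
    Subject,
    dimensionless_speed,
)
from .normative import (
    OrderRepairWarning,
    complete_derivatives,
    load_published_table,
    repair_timing_order,
)
from .reconstruct import reconstruct_waveform
from .regress import CoefficientTable
from .discretise import builtin_schema

__all__ = [
    "SynthConfig",
    "SynthTrial",
    "SyntheticDataset",
    "sample_population",
    "assign_conditions",
    "simulate_trial",
    "generate_dataset",
]

#: Imposed speed bands for conditions C1-C3, m/s.
CONDITION_BANDS = ((0.0, 0.4), (0.4, 0.8), (0.8, 1.2))

#: Spontaneous (C4) and maximal (C5) self-selected speeds, m/s:
#: mean / SD stand-ins from adult treadmill-overground norms.
SPONTANEOUS_SPEED = (1.3, 0.15)
MAXIMAL_SPEED = (1.9, 0.2)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic study; defaults are the study design."""

    seed: int
    n_subjects: int = 54
    trials_per_condition: int = 5
    noise_scale: float = 1.0
    waveform_noise_sd: float = 0.0
    waveform_noise_harmonics: int = 6
    age_mean: float = 37.9
    age_sd: float = 13.7
    age_range: Tuple[float, float] = (19.0, 67.0)
    p_male: float = 30 / 54
    height_mean: float = 1.74
    height_sd: float = 0.10
    bmi_mean: float = 24.0
    bmi_sd: float = 3.0
    bmi_range: Tuple[float, float] = (17.0, 31.0)
    leg_length_ratio: float = 0.53
    leg_length_jitter: float = 0.01

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.noise_scale < 0 or self.waveform_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k) for k in self.__dataclass_fields__
        }
        d["age_range"] = list(self.age_range)
        d["bmi_range"] = list(self.bmi_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        d["bmi_range"] = tuple(d["bmi_range"])
        return cls(**d)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Truncated normal draws whose post-truncation mean equals ``mean``.

    Truncating an asymmetric range shifts the mean (e.g. ages 19-67 around
    37.9 pull upwards), so the location parameter is calibrated such that
    the reported population mean holds after truncation.
    """
    from scipy.optimize import brentq

    def shifted_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd)) - mean

    loc = brentq(shifted_mean, lo - sd, hi + sd, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def sample_population(config: SynthConfig) -> List[Subject]:
    """Draw a synthetic population matching the study demographics."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_subjects
    ages = _truncated_normal(
        rng, config.age_mean, config.age_sd, *config.age_range, size=n
    )
    sexes = (rng.random(n) < config.p_male).astype(int)
    heights = rng.normal(config.height_mean, config.height_sd, size=n)
    heights = np.clip(heights, 1.40, 2.10)
    bmis = _truncated_normal(
        rng, config.bmi_mean, config.bmi_sd, *config.bmi_range, size=n
    )
    leg_ratio = config.leg_length_ratio * (
        1.0 + rng.normal(0.0, config.leg_length_jitter, size=n)
    )
    subjects = []
    for i in range(n):
        height = float(heights[i])
        bmi = float(bmis[i])
        subjects.append(
            Subject(
                id=f"S{i + 1:03d}",
                age=float(ages[i]),
                sex=int(sexes[i]),
                bmi=bmi,
                leg_length=float(leg_ratio[i] * height),
                height=height,
                mass=bmi * height**2,
            )
        )
    return subjects


def assign_conditions(
    subject: Subject, rng: np.random.Generator
) -> List[float]:
    """Five target walking speeds (m/s) for one subject: C1-C3 uniform in
    the imposed bands, C4 spontaneous, C5 maximal self-selected."""
    speeds = [float(rng.uniform(lo, hi)) for lo, hi in CONDITION_BANDS]
    speeds.append(float(max(0.6, rng.normal(*SPONTANEOUS_SPEED))))
    speeds.append(float(max(0.8, rng.normal(*MAXIMAL_SPEED))))
    return speeds


@dataclass(frozen=True)
class SynthTrial:
    """One generated gait trial: predictors, events, key-points, waveforms."""

    trial_id: int
    subject_id: str
    condition: int  # 1..5
    trial_index: int  # 1..trials_per_condition
    speed_ms: float
    predictor: PredictorVector
    events: GaitEvents
    keypoints: Dict[str, List[KeyPointState]]
    waveforms: Dict[str, GaitWaveform]


def _band_limited_noise(
    rng: np.random.Generator, sd: float, harmonics: int
) -> np.ndarray:
    """Smooth zero-mean periodic noise over the 101-sample cycle."""
    phase = 2.0 * np.pi * np.arange(N_SAMPLES) / 100.0
    sigma = sd / np.sqrt(harmonics)
    noise = np.zeros(N_SAMPLES)
    for k in range(1, harmonics + 1):
        a, b = rng.normal(0.0, sigma, size=2)
        noise += a * np.cos(k * phase) + b * np.sin(k * phase)
    return noise


def _trial_events(table: CoefficientTable, p: PredictorVector) -> GaitEvents:
    # foot off from its (noiseless) timing equation; contralateral events by
    # half-cycle symmetry of steady gait
    ifo_sample = table.get("HIS4", "timing").predict(p)
    ifo_pct = float(np.clip(ifo_sample - 1.0, 52.0, 75.0))
    return GaitEvents(
        contralateral_foot_off=ifo_pct - 50.0,
        contralateral_foot_strike=50.0,
        ipsilateral_foot_off=ifo_pct,
    )


def simulate_trial(
    subject: Subject,
    v_star: float,
    config: SynthConfig,
    table: CoefficientTable,
    rng: np.random.Generator,
    trial_id: int = 0,
    condition: int = 0,
    trial_index: int = 0,
    speed_ms: float = float("nan"),
) -> SynthTrial:
    """Generate one trial at dimensionless speed ``v_star``.

    Key-point parameters are the generating-table predictions plus
    ``Normal(0, noise_scale * equation RMSE)``; the cycle-end key-point
    copies the cycle-start draw, timings are ordering-repaired, and the
    waveforms are rebuilt through the quintic pipeline.
    """
    p = PredictorVector(v_star=v_star, age=subject.age, sex=subject.sex, bmi=subject.bmi)
    events = _trial_events(table, p)
    keypoints: Dict[str, List[KeyPointState]] = {}
    waveforms: Dict[str, GaitWaveform] = {}
    for joint in JOINTS:
        ids = builtin_schema(joint).ids
        states = []
        for kp_id in ids:
            values = {}
            for param in ("timing", "angle"):
                rec = table.get(kp_id, param)
                val = rec.predict(p)
                if config.noise_scale > 0 and not rec.is_constant and rec.rmse > 0:
                    val += rng.normal(0.0, config.noise_scale * rec.rmse)
                values[param] = val
            timing = float(np.clip(values["timing"], 1.0, float(N_SAMPLES)))
            states.append(KeyPointState(kp_id, timing, values["angle"]))
        # cycle-end repeats cycle-start (continuity across cycles)
        states[-1] = KeyPointState(
            states[-1].keypoint_id, float(N_SAMPLES), states[0].angle
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrderRepairWarning)
            states = repair_timing_order(states)
        states = complete_derivatives(states)
        keypoints[joint] = states
        wf = reconstruct_waveform(states, joint=joint)
        if config.waveform_noise_sd > 0:
            noise = _band_limited_noise(
                rng, config.waveform_noise_sd, config.waveform_noise_harmonics
            )
            wf = GaitWaveform(joint=joint, values=wf.values + noise, side=wf.side)
        waveforms[joint] = wf
    return SynthTrial(
        trial_id=trial_id,
        subject_id=subject.id,
        condition=condition,
        trial_index=trial_index,
        speed_ms=speed_ms,
        predictor=p,
        events=events,
        keypoints=keypoints,
        waveforms=waveforms,
    )


@dataclass
class SyntheticDataset:
    """Subjects x conditions x trials with the generating table recorded."""

    config: SynthConfig
    subjects: List[Subject]
    trials: List[SynthTrial]
    generating_table: CoefficientTable

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)

    def predictor_frame(self) -> pd.DataFrame:
        """One row per trial: speed (dimensionless), age, sex, bmi."""
        rows = {
            t.trial_id: {
                "speed": t.predictor.v_star,
                "age": t.predictor.age,
                "sex": float(t.predictor.sex),
                "bmi": t.predictor.bmi,
            }
            for t in self.trials
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "trial"
        return df

    def keypoint_frame(self) -> pd.DataFrame:
        """Long frame: trial, joint, keypoint_id, timing, angle, derivatives."""
        rows = []
        for t in self.trials:
            for joint, states in t.keypoints.items():
                for s in states:
                    rows.append(
                        {
                            "trial": t.trial_id,
                            "joint": joint,
                            "keypoint_id": s.keypoint_id,
                            "timing": s.timing,
                            "angle": s.angle,
                            "velocity": s.velocity,
                            "acceleration": s.acceleration,
                        }
                    )
        return pd.DataFrame(rows)

    def save(self, directory) -> None:
        """Write the dataset as a directory of CSV files plus a manifest."""
        from .io import write_coefficient_table

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "id": s.id,
                    "age": s.age,
                    "sex": s.sex,
                    "bmi": s.bmi,
                    "leg_length": s.leg_length,
                    "height": s.height,
                    "mass": s.mass,
                }
                for s in self.subjects
            ]
        ).to_csv(directory / "subjects.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            [
                {
                    "trial": t.trial_id,
                    "subject_id": t.subject_id,
                    "condition": t.condition,
                    "trial_index": t.trial_index,
                    "speed_ms": t.speed_ms,
                    "v_star": t.predictor.v_star,
                    "age": t.predictor.age,
                    "sex": t.predictor.sex,
                    "bmi": t.predictor.bmi,
                    "contralateral_foot_off": t.events.contralateral_foot_off,
                    "contralateral_foot_strike": t.events.contralateral_foot_strike,
                    "ipsilateral_foot_off": t.events.ipsilateral_foot_off,
                }
                for t in self.trials
            ]
        ).to_csv(directory / "trials.csv", index=False, float_format="%.17g")
        self.keypoint_frame().to_csv(
            directory / "keypoints.csv", index=False, float_format="%.17g"
        )
        wf_rows = []
        for t in self.trials:
            for joint, wf in t.waveforms.items():
                for k, angle in enumerate(wf.values, start=1):
                    wf_rows.append((t.trial_id, joint, k, angle))
        pd.DataFrame(
            wf_rows, columns=["trial", "joint", "sample", "angle_deg"]
        ).to_csv(directory / "waveforms.csv", index=False, float_format="%.17g")
        write_coefficient_table(self.generating_table, directory / "generating_table.csv")
        (directory / "manifest.json").write_text(
            json.dumps({"config": self.config.to_dict()}, indent=2)
        )

    @classmethod
    def load(cls, directory) -> "SyntheticDataset":
        from .io import read_coefficient_table

        directory = Path(directory)
        config = SynthConfig.from_dict(
            json.loads((directory / "manifest.json").read_text())["config"]
        )
        subjects = [
            Subject(
                id=row["id"],
                age=row["age"],
                sex=int(row["sex"]),
                bmi=row["bmi"],
                leg_length=row["leg_length"],
                height=row["height"],
                mass=row["mass"],
            )
            for _, row in pd.read_csv(directory / "subjects.csv", float_precision="round_trip").iterrows()
        ]
        table = read_coefficient_table(directory / "generating_table.csv")
        kp_df = pd.read_csv(directory / "keypoints.csv", float_precision="round_trip")
        wf_df = pd.read_csv(directory / "waveforms.csv", float_precision="round_trip")
        trials = []
        trials_df = pd.read_csv(directory / "trials.csv", float_precision="round_trip")
        kp_groups = dict(tuple(kp_df.groupby("trial", sort=False)))
        wf_groups = dict(tuple(wf_df.groupby("trial", sort=False)))
        for _, row in trials_df.iterrows():
            tid = int(row["trial"])
            keypoints: Dict[str, List[KeyPointState]] = {}
            for joint, jg in kp_groups[tid].groupby("joint", sort=False):
                keypoints[joint] = [
                    KeyPointState(
                        r["keypoint_id"],
                        r["timing"],
                        r["angle"],
                        None if pd.isna(r["velocity"]) else r["velocity"],
                        None if pd.isna(r["acceleration"]) else r["acceleration"],
                    )
                    for _, r in jg.iterrows()
                ]
            waveforms = {
                joint: GaitWaveform(
                    joint=joint,
                    values=jg.sort_values("sample")["angle_deg"].to_numpy(),
                )
                for joint, jg in wf_groups[tid].groupby("joint", sort=False)
            }
            trials.append(
                SynthTrial(
                    trial_id=tid,
                    subject_id=row["subject_id"],
                    condition=int(row["condition"]),
                    trial_index=int(row["trial_index"]),
                    speed_ms=float(row["speed_ms"]),
                    predictor=PredictorVector(
                        v_star=float(row["v_star"]),
                        age=float(row["age"]),
                        sex=int(row["sex"]),
                        bmi=float(row["bmi"]),
                    ),
                    events=GaitEvents(
                        contralateral_foot_off=float(row["contralateral_foot_off"]),
                        contralateral_foot_strike=float(
                            row["contralateral_foot_strike"]
                        ),
                        ipsilateral_foot_off=float(row["ipsilateral_foot_off"]),
                    ),
                    keypoints=keypoints,
                    waveforms=waveforms,
                )
            )
        return cls(
            config=config, subjects=subjects, trials=trials, generating_table=table
        )


def generate_dataset(
    config: SynthConfig, table: Optional[CoefficientTable] = None
) -> SyntheticDataset:
    """Generate the full subjects x conditions x trials dataset."""
    if table is None:
        table = load_published_table()
    subjects = sample_population(config)
    trials: List[SynthTrial] = []
    trial_id = 0
    for si, subject in enumerate(subjects):
        cond_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, si]))
        speeds = assign_conditions(subject, cond_rng)
        for ci, v in enumerate(speeds):
            v_star = dimensionless_speed(v, subject.leg_length)
            for ti in range(config.trials_per_condition):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 3, si, ci, ti])
                )
                trials.append(
                    simulate_trial(
                        subject,
                        v_star,
                        config,
                        table,
                        rng,
                        trial_id=trial_id,
                        condition=ci + 1,
                        trial_index=ti + 1,
                        speed_ms=v,
                    )
                )
                trial_id += 1
    return SyntheticDataset(
        config=config, subjects=subjects, trials=trials, generating_table=table
    )
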