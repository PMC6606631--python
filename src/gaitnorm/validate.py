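"""Leave-one-out cross validation of the prediction pipeline.

Each subject is held out in turn; the regression equations are re-fitted
on everyone else, the held-out subject's waveforms are predicted at their
own predictor values, and prediction quality is scored per waveform with
RMSE (degrees), the squared Pearson correlation R^2, and the Variance
Accounted For, ``VAF = 100 * (1 - var(y - yhat) / var(y))`` (population
variances; offset-insensitive, unlike RMSE).  Summaries are binned by
dimensionless speed (bin width 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .normative import ExtrapolationWarning, OrderRepairWarning, predict_waveforms
from .reconstruct import waveform_rmse
from .regress import fit_dataset
from .synth import SyntheticDataset

__all__ = ["ValidationResult", "LoocvResult", "vaf", "r_squared", "loocv"]

SPEED_BIN_WIDTH = 0.05


def vaf(y: np.ndarray, yhat: np.ndarray) -> float:
    """Variance Accounted For, %: ``100 * (1 - var(y - yhat) / var(y))``.

    Insensitive to a constant offset between the curves.  Returns NaN when
    the reference waveform has zero variance (undefined metric).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("waveforms must share a length of at least 2")
    denom = np.var(y)
    if denom == 0:
        return float("nan")
    return float(100.0 * (1.0 - np.var(y - yhat) / denom))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation between measured and predicted curves.

    Returns NaN when either input is constant (correlation undefined).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("waveforms must share a length of at least 2")
    if np.var(y) == 0 or np.var(yhat) == 0:
        return float("nan")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ValidationResult:
    """Goodness of fit for one held-out waveform."""

    subject_id: str
    trial_id: int
    condition: int
    v_star: float
    joint: str
    rmse: float
    r2: float
    vaf: float


@dataclass
class LoocvResult:
    """All per-waveform scores plus speed-binned summaries."""

    records: List[ValidationResult]
    failed_folds: List[str]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def summary(self) -> pd.DataFrame:
        """Mean/SD of each metric per (speed bin, joint)."""
        df = self.frame
        df = df.assign(
            speed_bin=np.floor(df["v_star"] / SPEED_BIN_WIDTH) * SPEED_BIN_WIDTH
        )
        return (
            df.groupby(["speed_bin", "joint"])[["rmse", "r2", "vaf"]]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


def loocv(
    dataset: SyntheticDataset,
    alpha: float = 0.01,
    parameters: Sequence[str] = ("timing", "angle"),
) -> LoocvResult:
    """Leave-one-subject-out cross validation over a trial database.

    The hold-out unit is the subject: all of a participant's trials leave
    the training set together.  A fold whose fit fails is flagged and the
    remaining folds proceed.
    """
    subject_ids = [s.id for s in dataset.subjects]
    if len(subject_ids) < 3:
        raise ValueError(
            f"leave-one-out needs at least 3 subjects, got {len(subject_ids)}"
        )
    predictors = dataset.predictor_frame()
    keypoints = dataset.keypoint_frame()
    trial_subject = {t.trial_id: t.subject_id for t in dataset.trials}

    records: List[ValidationResult] = []
    failed: List[str] = []
    for held_out in subject_ids:
        train_ids = [tid for tid, sid in trial_subject.items() if sid != held_out]
        test_trials = [t for t in dataset.trials if t.subject_id == held_out]
        assert not {t.trial_id for t in test_trials} & set(train_ids)
        try:
            table = fit_dataset(
                predictors.loc[train_ids],
                keypoints[keypoints["trial"].isin(train_ids)],
                alpha=alpha,
                parameters=parameters,
            )
        except Exception as exc:  # fold-level failure must not sink the rest
            warnings.warn(f"fold {held_out}: fit failed ({exc})", RuntimeWarning)
            failed.append(held_out)
            continue
        for trial in test_trials:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                warnings.simplefilter("ignore", OrderRepairWarning)
                predicted = predict_waveforms(table, trial.predictor)
            for joint, wf_pred in predicted.items():
                wf_true = trial.waveforms[joint]
                records.append(
                    ValidationResult(
                        subject_id=held_out,
                        trial_id=trial.trial_id,
                        condition=trial.condition,
                        v_star=trial.predictor.v_star,
                        joint=joint,
                        rmse=waveform_rmse(wf_true, wf_pred),
                        r2=r_squared(wf_true.values, wf_pred.values),
                        vaf=vaf(wf_true.values, wf_pred.values),
                    )
                )
    return LoocvResult(records=records, failed_folds=failed)
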