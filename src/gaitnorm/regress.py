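"""Per-key-point regression equations on speed, age, sex and BMI.

Every key-point parameter (timing on the 1..101 scale, angle in degrees,
optionally angular velocity/acceleration) gets its own multilinear
equation.  Predictors are screened by forward-backward stepwise selection
on partial t-test p-values (entry and removal both at alpha = 0.01); the
retained design is then fitted by iteratively reweighted least squares
with a Tukey bisquare weight (tuning constant 4.685, residual scale
MAD/0.6745), which down-weights outlying trials.  Non-retained predictors
are exactly absent from prediction.

Cycle-boundary timings are structural constants (sample 1 and 101) and are
emitted as constant records rather than fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import PredictorVector

__all__ = [
    "PREDICTORS",
    "RegressionRecord",
    "CoefficientTable",
    "stepwise_select",
    "robust_fit",
    "fit_dataset",
]

#: Canonical predictor order (dimensionless speed first).
PREDICTORS = ("speed", "age", "sex", "bmi")

PARAMETERS = ("timing", "angle", "velocity", "acceleration")

#: Key-points whose timing is pinned to the cycle boundary.
CONSTANT_START = frozenset({"HIS1", "KNS1", "ANS1"})
CONSTANT_END = frozenset({"HIS6", "KNS8", "ANS7"})

_PREFIX_JOINT = {"HIS": "hip", "KNS": "knee", "ANS": "ankle"}


def joint_of(keypoint_id: str) -> str:
    """Joint a key-point id belongs to (HIS* -> hip, KNS* -> knee, ANS* -> ankle)."""
    try:
        return _PREFIX_JOINT[keypoint_id[:3]]
    except KeyError:
        raise ValueError(f"unknown key-point id {keypoint_id!r}") from None


@dataclass(frozen=True)
class RegressionRecord:
    """One fitted (or published) equation for one key-point parameter.

    ``coefficients`` holds only the retained predictors; a predictor absent
    from the mapping was not significant and contributes exactly zero.
    """

    keypoint_id: str
    parameter: str
    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    rmse: float = float("nan")
    is_constant: bool = False
    unfit: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        bad = set(self.coefficients) - set(PREDICTORS)
        if bad:
            raise ValueError(f"unknown predictors {sorted(bad)}")
        if self.is_constant and self.coefficients:
            raise ValueError("constant records cannot carry predictors")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    @property
    def n_predictors(self) -> int:
        return len(self.coefficients)

    def retained(self, predictor: str) -> bool:
        return predictor in self.coefficients

    def predict(self, p: PredictorVector) -> float:
        """Evaluate the equation at a predictor vector (raw units)."""
        if self.unfit:
            raise ValueError(
                f"{self.keypoint_id} {self.parameter}: record flagged unfit"
            )
        if self.is_constant:
            return self.intercept
        values = {"speed": p.v_star, "age": p.age, "sex": float(p.sex), "bmi": p.bmi}
        return self.intercept + sum(
            beta * values[name] for name, beta in self.coefficients.items()
        )


class CoefficientTable:
    """Collection of regression records keyed by (key-point, parameter)."""

    def __init__(
        self,
        records: Iterable[RegressionRecord] = (),
        source: str = "fitted",
    ) -> None:
        self.source = source
        self._records: Dict[Tuple[str, str], RegressionRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: RegressionRecord) -> None:
        key = (record.keypoint_id, record.parameter)
        if key in self._records:
            raise ValueError(f"duplicate record for {key}")
        self._records[key] = record

    def get(self, keypoint_id: str, parameter: str) -> RegressionRecord:
        try:
            return self._records[(keypoint_id, parameter)]
        except KeyError:
            raise KeyError(
                f"no record for key-point {keypoint_id!r}, parameter {parameter!r}"
            ) from None

    def has(self, keypoint_id: str, parameter: str) -> bool:
        return (keypoint_id, parameter) in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def keypoint_ids(self) -> Tuple[str, ...]:
        seen = dict.fromkeys(kp for kp, _ in self._records)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per record, NaN marking non-significant."""
        rows = []
        for rec in self._records.values():
            row = {
                "joint": joint_of(rec.keypoint_id),
                "keypoint_id": rec.keypoint_id,
                "parameter": rec.parameter,
                "beta0": rec.intercept,
            }
            for name in PREDICTORS:
                row[f"beta_{name}"] = rec.coefficients.get(name, np.nan)
            row["rmse"] = rec.rmse
            row["n_predictors"] = rec.n_predictors
            row["is_constant"] = rec.is_constant
            rows.append(row)
        return pd.DataFrame(rows)


def _pvalues_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values for an OLS fit with intercept prepended.

    NaN p-values (zero residual variance with a zero coefficient) are
    mapped to 1.0: such a predictor explains nothing that is left.  When
    the fit is exact to machine precision the leftover residual is
    floating-point rounding, not data, and t-tests on it are meaningless;
    a predictor then counts as significant only if its effect rises above
    the numeric noise floor.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 0 or X.shape[0] != len(y):
        X = X.reshape(len(y), -1)
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sm.OLS(y, design).fit()
            pvals = np.asarray(res.pvalues, dtype=float)
    floor = 1e-8 * max(1.0, float(np.max(np.abs(y))) if len(y) else 1.0)
    if np.sqrt(max(res.mse_resid, 0.0)) <= floor:
        col_scale = np.concatenate([[1.0], np.std(X, axis=0)])
        effects = np.abs(np.asarray(res.params, dtype=float)) * col_scale
        pvals = np.where(effects > floor, 0.0, 1.0)
    return np.where(np.isnan(pvals), 1.0, pvals)


def stepwise_select(
    design: np.ndarray, response: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Forward-backward stepwise predictor selection at threshold ``alpha``.

    Starts from the intercept-only model.  Each forward step adds the
    candidate with the smallest partial t-test p-value if it is below
    ``alpha`` (ties broken by the canonical speed -> age -> sex -> BMI scan
    order); each backward step removes the in-model predictor with the
    largest p-value if it reaches ``alpha``.  Returns a boolean mask over
    the design columns.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D (trials x predictors)")
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} rows for {k} predictors, got {n}")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("design contains constant predictor columns")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < k + 1:
        raise np.linalg.LinAlgError(
            "rank-deficient design: predictors are collinear"
        )

    selected: list[int] = []
    for _ in range(4 * k + 4):
        changed = False
        # forward: best candidate by (p-value, scan order)
        candidates = [j for j in range(k) if j not in selected]
        if candidates:
            best_j, best_p = None, np.inf
            for j in candidates:
                p = _pvalues_ols(X[:, selected + [j]], y)[-1]
                if p < best_p:
                    best_j, best_p = j, p
            if best_p < alpha:
                selected.append(best_j)
                changed = True
        # backward: drop the worst retained predictor if it lost significance
        if selected:
            pvals = _pvalues_ols(X[:, selected], y)[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] >= alpha:
                del selected[worst]
                changed = True
        if not changed:
            break

    mask = np.zeros(k, dtype=bool)
    mask[selected] = True
    return mask


def robust_fit(
    design: np.ndarray,
    response: np.ndarray,
    tuning: float = 4.685,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> Tuple[np.ndarray, dict]:
    """IRLS with Tukey bisquare weights on a full design (intercept included).

    Residual scale is re-estimated each iteration as MAD/0.6745; residuals
    beyond ``tuning`` scaled units get zero weight.  Converges when the
    largest coefficient update falls below ``tol``.  On exactly fitting
    data the scale collapses to zero and the ordinary least squares
    solution is returned with unit weights.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("robust_fit requires a full-rank design")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    weights = np.ones(n)
    converged = False
    iterations = 0
    scale_floor = 1e-12 * max(1.0, float(np.max(np.abs(y))) if n else 1.0)
    for iterations in range(1, max_iter + 1):
        r = y - X @ beta
        med = np.median(r)
        s = np.median(np.abs(r - med)) / 0.6745
        if s <= scale_floor:
            weights = np.ones(n)
            converged = True
            break
        u = r / (tuning * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if not np.any(w > 0):  # pathological: all points rejected
            converged = True
            break
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta, weights = beta_new, w
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"robust_fit did not converge in {max_iter} iterations",
            RuntimeWarning,
        )
    residuals = y - X @ beta
    info = {
        "weights": weights,
        "iterations": iterations,
        "converged": converged,
        "rmse": float(np.sqrt(np.mean(residuals**2))),
        "residuals": residuals,
    }
    return beta, info


def fit_dataset(
    predictors: pd.DataFrame,
    keypoints: pd.DataFrame,
    alpha: float = 0.01,
    parameters: Sequence[str] = ("timing", "angle"),
) -> CoefficientTable:
    """Fit one equation per (key-point, parameter) over a trial database.

    Parameters
    ----------
    predictors : DataFrame indexed by trial id with columns
        ``speed`` (dimensionless), ``age``, ``sex``, ``bmi``.
    keypoints : long DataFrame with columns ``trial``, ``keypoint_id`` and
        one column per parameter (``timing``, ``angle``, ...).
    alpha : stepwise entry/removal threshold.
    parameters : which key-point parameters to model; velocity and
        acceleration equations are only fitted when their columns exist.

    Cycle-boundary timings are emitted as constants (1 / 101).  Equations
    with too few rows are flagged unfit rather than fitted.
    """
    missing = [c for c in PREDICTORS if c not in predictors.columns]
    if missing:
        raise ValueError(f"predictor frame lacks columns {missing}")
    table = CoefficientTable(source="fitted")
    for kp_id, group in keypoints.groupby("keypoint_id", sort=False):
        X = predictors.loc[group["trial"], list(PREDICTORS)].to_numpy(dtype=float)
        for param in parameters:
            if param not in group.columns:
                continue
            y = group[param].to_numpy(dtype=float)
            if np.all(np.isnan(y)):
                continue
            if param == "timing" and kp_id in CONSTANT_START:
                table.add(
                    RegressionRecord(kp_id, param, 1.0, {}, rmse=0.0, is_constant=True)
                )
                continue
            if param == "timing" and kp_id in CONSTANT_END:
                table.add(
                    RegressionRecord(kp_id, param, 101.0, {}, rmse=0.0, is_constant=True)
                )
                continue
            if len(y) < X.shape[1] + 2:
                warnings.warn(
                    f"{kp_id} {param}: only {len(y)} rows, record flagged unfit",
                    RuntimeWarning,
                )
                table.add(
                    RegressionRecord(kp_id, param, float("nan"), {}, unfit=True)
                )
                continue
            mask = stepwise_select(X, y, alpha=alpha)
            names = [nm for nm, keep in zip(PREDICTORS, mask) if keep]
            design = np.column_stack([np.ones(len(y)), X[:, mask]])
            beta, info = robust_fit(design, y)
            table.add(
                RegressionRecord(
                    keypoint_id=kp_id,
                    parameter=param,
                    intercept=float(beta[0]),
                    coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
                    rmse=info["rmse"],
                    converged=info["converged"],
                )
            )
    return table
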