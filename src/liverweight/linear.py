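"""Ordinary least squares, prediction, and the accuracy/parsimony metrics.

The candidate estimation formulas are plain linear models

    graft weight [g] = a + b1*x1 (+ b2*x2)

and model quality is judged on the gram scale by the root-mean-square error
(RMSE) rather than R^2, so that an accuracy difference between candidates is
readable as grams of graft weight.  Parsimony is priced by the cost function

    C = R * (1 + 0.05 * (N - 1))

where R is the (cross-validated) RMSE and N the number of predictors: a
second predictor must buy roughly a 5% RMSE reduction to be worth keeping.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, VARIABLE_PRIORITY

#: Relative condition threshold on the design's singular values beyond which
#: a candidate is declared rank-deficient (e.g. a constant predictor, or two
#: exactly proportional BSA columns).
COND_THRESHOLD = 1e10


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is numerically rank-deficient; the candidate is flagged
    invalid rather than silently fitted."""


@dataclass(frozen=True)
class FittedLinearModel:
    """Intercept + coefficients of a fitted candidate formula.

    ``intercept`` is in grams; each coefficient is grams per unit of its
    predictor (g/kg for bw, g/m**2 for the BSAs, ...).  Sex enters as an
    indicator (female=1, male=0).
    """

    intercept: float
    coefficients: dict[str, float]
    predictor_names: tuple[str, ...]
    n_fit: int

    def __post_init__(self):
        if set(self.coefficients) != set(self.predictor_names):
            raise ValueError("coefficients must be keyed exactly by predictor_names")
        if not 1 <= len(self.predictor_names) <= 2:
            raise ValueError("candidate formulas use 1 or 2 predictors")

    def formula_string(self, decimals: int = 1) -> str:
        """Display form with coefficients rounded, e.g.
        'graft weight [g] = 14.8 x bw + 439.2'."""
        terms = " + ".join(
            f"{round(self.coefficients[p], decimals)} x {p}" for p in self.predictor_names
        )
        return f"graft weight [g] = {terms} + {round(self.intercept, decimals)}"

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "predictor_names": list(self.predictor_names),
                "n_fit": self.n_fit,
            },
            **kwargs,
        )

    @classmethod
    def from_json(cls, s: str) -> "FittedLinearModel":
        d = json.loads(s)
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            predictor_names=tuple(d["predictor_names"]),
            n_fit=d["n_fit"],
        )


@dataclass(frozen=True)
class AccuracyMetrics:
    rmse: float  # grams
    r_squared: float
    n: int


def _design(cohort: Cohort, predictors: tuple[str, ...]) -> np.ndarray:
    X = cohort.design_matrix()
    missing = [p for p in predictors if p not in X.columns]
    if missing:
        raise KeyError(f"unknown predictors {missing}; choose from {list(VARIABLE_PRIORITY)}")
    return np.column_stack([np.ones(len(X)), X[list(predictors)].to_numpy(float)])


def fit_ols(
    cohort: Cohort,
    predictors,
    cond_threshold: float = COND_THRESHOLD,
) -> FittedLinearModel:
    """Least-squares fit of graft weight on the given predictor subset.

    Raises ``RankDeficientError`` when the ratio of the design's largest to
    smallest singular value exceeds ``cond_threshold``.
    """
    predictors = tuple(predictors)
    if len(cohort) <= len(predictors) + 1:
        raise ValueError(
            f"cohort of size {len(cohort)} too small to fit {len(predictors)} predictors"
        )
    Z = _design(cohort, predictors)
    y = cohort.y
    beta, _, rank, sv = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1] or sv[0] > cond_threshold * sv[-1]:
        raise RankDeficientError(
            f"rank-deficient design for candidate {predictors}: "
            f"singular-value ratio {sv[0] / max(sv[-1], np.finfo(float).tiny):.3g}"
        )
    return FittedLinearModel(
        intercept=float(beta[0]),
        coefficients={p: float(b) for p, b in zip(predictors, beta[1:])},
        predictor_names=predictors,
        n_fit=len(cohort),
    )


def predict(model: FittedLinearModel, cohort: Cohort) -> np.ndarray:
    """Per-record estimate, grams: yhat = a + sum(b * x)."""
    Z = _design(cohort, model.predictor_names)
    beta = np.array([model.intercept] + [model.coefficients[p] for p in model.predictor_names])
    return Z @ beta


def rmse(observed, predicted, n_params: int | None = None) -> float:
    """Root-mean-square error, grams: sqrt(mean((y - yhat)**2)).

    The divisor is n (a plain summary of residuals).  Passing ``n_params``
    switches to the regression convention n - p for comparison purposes.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    ss = float(np.sum((y - yhat) ** 2))
    denom = y.size if n_params is None else y.size - n_params
    if denom <= 0:
        raise ValueError("n - n_params must be positive")
    return float(np.sqrt(ss / denom))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    May be negative when a fixed external formula predicts worse than the
    cohort mean.  Raises on constant ``observed`` (SStot = 0, undefined).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("observed values are constant; R^2 undefined")
    ssres = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssres / sstot


def accuracy(observed, predicted) -> AccuracyMetrics:
    return AccuracyMetrics(
        rmse=rmse(observed, predicted),
        r_squared=r_squared(observed, predicted),
        n=int(np.asarray(observed).size),
    )


def parsimony_cost(rmse_value: float, n_vars: int) -> float:
    """Complexity-penalized cost C = R * (1 + 0.05 * (N - 1)).

    With one predictor the cost is the RMSE itself; each further predictor
    inflates the effective RMSE by 5%, so a bivariable candidate displaces a
    univariable one only when its RMSE times 1.05 still undercuts it.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if rmse_value < 0:
        raise ValueError("rmse must be >= 0")
    return rmse_value * (1.0 + 0.05 * (n_vars - 1))
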