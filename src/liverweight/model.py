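"""statsmodels-style facade: a Model built from a cohort whose ``fit()``
returns a Results object carrying the selected formula, vote distribution,
in-sample accuracy and a ``summary()`` table; nested cross-validation hangs
off the same objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort, VARIABLE_PRIORITY, read_cohort
from .linear import AccuracyMetrics, FittedLinearModel, accuracy, predict
from .nested import NestedCVResult, bootstrap_r2_interval, run_outer_cv
from .selection import (
    CandidateSpec,
    CVConfig,
    InnerCVResult,
    SelectionResult,
    enumerate_candidates,
    fit_final,
    run_inner_cv,
    vote_selection,
)


class GraftWeightModel:
    """Parsimony-constrained graft-weight formula selector.

    Parameters
    ----------
    cohort : Cohort
        Donor/graft cohort (see :func:`liverweight.read_cohort`).
    variables : sequence of str, optional
        Candidate predictors; defaults to all six
        (bw, bsa_dubois, bsa_mosteller, bh, age, sex).
    max_vars : int
        Largest candidate size (1 or 2; default 2).
    inner_cv : CVConfig, optional
        Inner cross-validation settings (default 10 folds x 10 repeats,
        5% RMSE rule).
    """

    def __init__(self, cohort: Cohort, variables=None, max_vars: int = 2,
                 inner_cv: CVConfig | None = None):
        self.cohort = cohort
        self.variables = tuple(variables) if variables else VARIABLE_PRIORITY
        self.candidates = enumerate_candidates(self.variables, max_vars)
        self.inner_cv = inner_cv or CVConfig()

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "", **kwargs) -> "GraftWeightModel":
        return cls(Cohort.from_dataframe(df, label=label), **kwargs)

    @classmethod
    def from_file(cls, path, format: str = "delimited", mapping=None, **kwargs):
        return cls(read_cohort(path, format=format, mapping=mapping), **kwargs)

    # -- estimation ------------------------------------------------------------
    def fit(self, n_cycles: int = 100, subset_fraction: float = 0.9) -> "GraftWeightResults":
        """Run the voting selection and the final whole-data fit."""
        selection = vote_selection(self.cohort, self.candidates, self.inner_cv,
                                   n_cycles=n_cycles, subset_fraction=subset_fraction)
        final = fit_final(self.cohort, selection.winner)
        in_sample = accuracy(self.cohort.y, predict(final, self.cohort))
        inner = run_inner_cv(self.cohort, self.candidates, self.inner_cv)
        return GraftWeightResults(model=self, selection=selection, final_model=final,
                                  in_sample=in_sample, inner_cv=inner)

    def cross_validate(self, outer_cv: CVConfig | None = None, audit=None) -> NestedCVResult:
        """Nested CV of the whole selection procedure (external validity)."""
        outer = outer_cv or CVConfig(aggregation="pooled")
        return run_outer_cv(self.cohort, self.candidates,
                            inner_config=self.inner_cv, outer_config=outer,
                            audit=audit)


@dataclass
class GraftWeightResults:
    """Selection outcome: winning candidate, final formula, accuracy."""

    model: GraftWeightModel
    selection: SelectionResult
    final_model: FittedLinearModel
    in_sample: AccuracyMetrics
    inner_cv: InnerCVResult = field(repr=False, default=None)

    @property
    def winner(self) -> CandidateSpec:
        return self.selection.winner

    def bootstrap_r2(self, n_boot: int = 2000, level: float = 0.95, seed: int = 0):
        return bootstrap_r2_interval(self.model.cohort, self.winner,
                                     n_boot=n_boot, level=level, seed=seed)

    def candidate_table(self) -> pd.DataFrame:
        """Per-candidate mean/sd inner-CV RMSE and votes (chart-ready)."""
        votes = {c.name: v for c, v in self.selection.votes.items()}
        rows = []
        for cand, cv in self.inner_cv.per_candidate.items():
            rows.append({"candidate": cand.name, "n_vars": cand.n_vars,
                         "mean_cv_rmse": cv.mean_rmse, "sd_cv_rmse": cv.sd_rmse,
                         "valid": cv.valid, "votes": votes.get(cand.name, 0)})
        return pd.DataFrame(rows)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "winner": self.winner.name,
                "formula": self.final_model.formula_string(),
                "intercept": self.final_model.intercept,
                "coefficients": self.final_model.coefficients,
                "n_fit": self.final_model.n_fit,
                "in_sample_rmse": self.in_sample.rmse,
                "in_sample_r_squared": self.in_sample.r_squared,
                "votes": {c.name: v for c, v in self.selection.votes.items()},
                "n_cycles": self.selection.n_cycles,
            },
            **kwargs,
        )

    def summary(self) -> str:
        lines = [
            "Graft-weight formula selection",
            "=" * 64,
            f"cohort: n={len(self.model.cohort)}  label={self.model.cohort.label!r}",
            f"candidates: {len(self.model.candidates)}  "
            f"(inner CV {self.model.inner_cv.n_folds}x{self.model.inner_cv.n_repeats}, "
            f"{self.model.inner_cv.rmse_rule_threshold:.0%} RMSE rule)",
            "",
            f"winner: {self.winner.name}  "
            f"({self.selection.votes.get(self.winner, 0)}/{self.selection.n_cycles} votes)",
            f"final formula: {self.final_model.formula_string()}",
            f"in-sample RMSE: {self.in_sample.rmse:.1f} g    "
            f"R^2: {self.in_sample.r_squared:.3f}",
            "",
            "votes:",
        ]
        for name, v in self.selection.vote_table():
            lines.append(f"  {name:<28s} {v:>4d}")
        return "\n".join(lines)
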