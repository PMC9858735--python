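"""Outer repeated k-fold CV wrapping the whole selection procedure, plus a
bootstrap interval for the in-sample R^2.

The outer loop estimates the external validity of the *procedure* (inner CV +
parsimony rule + final fit), not of one fixed formula: inside every outer
training set the winning candidate is re-selected from scratch, fitted there,
and scored on the untouched outer test fold.  The spread of winning
candidates across outer training sets ("selection frequency") describes the
sampling variability of the selection itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .linear import FittedLinearModel, fit_ols, r_squared
from .selection import (
    CandidateSpec,
    CVConfig,
    _design_with_intercept,
    _run_inner_cv_arrays,
    apply_parsimony_rule,
)

logger = logging.getLogger(__name__)


@dataclass
class NestedCVResult:
    """Nested-CV estimate of out-of-sample accuracy and selection stability."""

    rmse: float  # grams, averaged over outer repeats
    r_squared: float
    selection_frequency: dict[CandidateSpec, float]
    per_repeat: pd.DataFrame  # columns: repeat, rmse, r_squared
    per_fold: pd.DataFrame  # columns: repeat, fold, candidate, test_rmse, n_test
    predictions: pd.DataFrame = field(repr=False, default=None)
    # columns: repeat, row, donor_id, actual, predicted

    def frequency_table(self) -> list[tuple[str, float]]:
        return sorted(((c.name, f) for c, f in self.selection_frequency.items()),
                      key=lambda t: (-t[1], t[0]))


def _fit_subset(Z, y, cand: CandidateSpec, cols_map) -> np.ndarray:
    cols = cols_map[cand]
    beta, _, _, _ = np.linalg.lstsq(Z[:, cols], y, rcond=None)
    return beta


def run_outer_cv(
    cohort: Cohort,
    candidates: list[CandidateSpec],
    inner_config: CVConfig,
    outer_config: CVConfig,
    audit=None,
) -> NestedCVResult:
    """Nested cross-validation of the full selection procedure.

    For every outer repeat the records are partitioned into
    ``outer_config.n_folds`` disjoint folds.  For each fold, the inner CV +
    parsimony rule run on the outer-training complement alone, the selected
    candidate is fitted there, and the held-out fold is predicted.  Per
    repeat, held-out predictions are pooled into one RMSE and R^2
    (``outer_config.aggregation == 'pooled'``, the default here) or averaged
    per fold ('per_fold'); the headline numbers are means across repeats.

    ``audit(repeat, fold, train_idx, test_idx)``, when given, is called once
    per outer fold with the global row indices used for selection+fitting and
    for testing — the two are always disjoint.
    """
    from .selection import _candidate_columns

    Z, y = _design_with_intercept(cohort)
    n = len(y)
    if n < outer_config.n_folds:
        raise ValueError("cohort smaller than the number of outer folds")
    cols_list = _candidate_columns(candidates)
    cols_map = dict(zip(candidates, cols_list))

    ss = np.random.SeedSequence(outer_config.seed)
    outer_rng = np.random.default_rng(ss.spawn(1)[0])
    inner_seeds = np.random.SeedSequence(inner_config.seed).spawn(
        outer_config.n_repeats * outer_config.n_folds
    )

    sel_counts: dict[CandidateSpec, int] = {}
    rep_rows, fold_rows, pred_rows = [], [], []
    donor_ids = cohort.df["donor_id"].to_numpy()

    for rep in range(outer_config.n_repeats):
        perm = outer_rng.permutation(n)
        folds = np.array_split(perm, outer_config.n_folds)
        sse_pool = 0.0
        sstot_pool = 0.0
        n_pool = 0
        fold_metrics = []
        for f_idx, fold in enumerate(folds):
            train = np.setdiff1d(perm, fold)
            if audit is not None:
                audit(rep, f_idx, train.copy(), fold.copy())
            inner_rng = np.random.default_rng(
                inner_seeds[rep * outer_config.n_folds + f_idx]
            )
            inner_res = _run_inner_cv_arrays(
                Z[train], y[train], candidates, inner_config, inner_rng
            )
            selected = apply_parsimony_rule(inner_res)
            sel_counts[selected] = sel_counts.get(selected, 0) + 1
            beta = _fit_subset(Z[train], y[train], selected, cols_map)
            preds = Z[fold][:, cols_map[selected]] @ beta
            resid = y[fold] - preds
            test_rmse = float(np.sqrt(np.mean(resid**2)))
            fold_rows.append(
                {"repeat": rep, "fold": f_idx, "candidate": selected.name,
                 "test_rmse": test_rmse, "n_test": len(fold)}
            )
            fold_metrics.append((test_rmse, resid, y[fold]))
            for i, row in enumerate(fold):
                pred_rows.append(
                    {"repeat": rep, "row": int(row), "donor_id": donor_ids[row],
                     "actual": float(y[row]), "predicted": float(preds[i])}
                )
            sse_pool += float(np.sum(resid**2))
            # SStot contribution uses the held-out fold's own mean
            sstot_pool += float(np.sum((y[fold] - y[fold].mean()) ** 2))
            n_pool += len(fold)
        if outer_config.aggregation == "pooled":
            rep_rmse = float(np.sqrt(sse_pool / n_pool))
            rep_r2 = 1.0 - sse_pool / sstot_pool
        else:
            per_fold_rmse = [m[0] for m in fold_metrics]
            rep_rmse = float(np.mean(per_fold_rmse))
            rep_r2 = float(
                np.mean([r_squared(yf, yf - res) for _, res, yf in fold_metrics])
            )
        rep_rows.append({"repeat": rep, "rmse": rep_rmse, "r_squared": rep_r2})

    per_repeat = pd.DataFrame(rep_rows)
    total_sets = outer_config.n_repeats * outer_config.n_folds
    freq = {c: v / total_sets for c, v in sel_counts.items()}
    return NestedCVResult(
        rmse=float(per_repeat["rmse"].mean()),
        r_squared=float(per_repeat["r_squared"].mean()),
        selection_frequency=freq,
        per_repeat=per_repeat,
        per_fold=pd.DataFrame(fold_rows),
        predictions=pd.DataFrame(pred_rows),
    )


def repeated_kfold_cv(
    cohort: Cohort, spec: CandidateSpec, config: CVConfig
) -> NestedCVResult:
    """Ordinary repeated k-fold CV of one fixed candidate (no inner
    selection); the degenerate case of :func:`run_outer_cv` with a single
    candidate."""
    return run_outer_cv(cohort, [spec], inner_config=config, outer_config=config)


def bootstrap_r2_interval(
    cohort: Cohort,
    spec: CandidateSpec,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the in-sample R^2 of one candidate.

    Each replicate resamples records with replacement, refits the candidate,
    and computes R^2 on the replicate itself.  Degenerate replicates
    (constant outcome or rank-deficient resampled design) are skipped and
    logged.
    """
    if len(cohort) < 10:
        raise ValueError("need at least 10 records for a bootstrap interval")
    from .selection import _candidate_columns

    Z, y = _design_with_intercept(cohort)
    cols = _candidate_columns([spec])[0]
    Zs = Z[:, cols]
    rng = np.random.default_rng(seed)
    n = len(y)
    stats = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        sstot = float(np.sum((yb - yb.mean()) ** 2))
        if sstot == 0.0:
            skipped += 1
            continue
        Zb = Zs[idx]
        beta, _, rank, _ = np.linalg.lstsq(Zb, yb, rcond=None)
        if rank < Zb.shape[1]:
            skipped += 1
            continue
        ssres = float(np.sum((yb - Zb @ beta) ** 2))
        stats.append(1.0 - ssres / sstot)
    if skipped:
        logger.warning("bootstrap_r2_interval: skipped %d degenerate replicates", skipped)
    if not stats:
        raise ValueError("all bootstrap replicates degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(stats), [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def fit_and_score_in_sample(cohort: Cohort, spec: CandidateSpec):
    """Convenience: final full-data fit with its in-sample RMSE/R^2."""
    from .linear import accuracy, predict

    model: FittedLinearModel = fit_ols(cohort, spec.predictors)
    metrics = accuracy(cohort.y, predict(model, cohort))
    return model, metrics
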