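"""Candidate enumeration, inner repeated k-fold CV, the 5% RMSE parsimony
rule, and subset voting.

The selection procedure evaluates every linear candidate with one or two
predictors drawn from {bw, bsa_dubois, bsa_mosteller, bh, age, sex} by
repeated k-fold cross-validation (default 10 folds x 10 repeats), then picks
the candidate minimizing the parsimony cost C = R(1 + 0.05(N-1)).  A second
predictor therefore survives only when it cuts the mean CV RMSE enough that
even after a 5% complexity surcharge it beats the best single-predictor
model.  The whole selection is wrapped in a voting loop: 100 cycles, each on
a fresh random 90% subsample, each casting one vote; the plurality winner is
refitted on the full data.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, VARIABLE_PRIORITY
from .linear import COND_THRESHOLD, FittedLinearModel, fit_ols, parsimony_cost

logger = logging.getLogger(__name__)

_PRIORITY_INDEX = {name: i for i, name in enumerate(VARIABLE_PRIORITY)}


@dataclass(frozen=True)
class CandidateSpec:
    """A set of 1-2 predictor names defining one linear candidate."""

    predictors: tuple[str, ...]

    def __post_init__(self):
        unknown = [p for p in self.predictors if p not in _PRIORITY_INDEX]
        if unknown:
            raise ValueError(f"unknown predictors {unknown}")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors")
        if not 1 <= len(self.predictors) <= 2:
            raise ValueError("candidates use 1 or 2 predictors")
        ordered = tuple(sorted(self.predictors, key=_PRIORITY_INDEX.__getitem__))
        object.__setattr__(self, "predictors", ordered)

    @property
    def n_vars(self) -> int:
        return len(self.predictors)

    @property
    def name(self) -> str:
        return "+".join(self.predictors)

    def priority_key(self) -> tuple:
        """Deterministic tie-break key: fewer variables first, then the fixed
        variable priority order."""
        return (self.n_vars, tuple(_PRIORITY_INDEX[p] for p in self.predictors))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


def enumerate_candidates(
    variables=VARIABLE_PRIORITY, max_vars: int = 2
) -> list[CandidateSpec]:
    """All predictor subsets of size 1..max_vars in deterministic order
    (by size, then fixed variable priority)."""
    variables = list(variables)
    if not variables:
        raise ValueError("empty variable list")
    if max_vars not in (1, 2):
        raise ValueError("max_vars must be 1 or 2")
    ordered = sorted(variables, key=_PRIORITY_INDEX.__getitem__)
    cands = [CandidateSpec((v,)) for v in ordered]
    if max_vars == 2:
        cands += [CandidateSpec(pair) for pair in itertools.combinations(ordered, 2)]
    return cands


@dataclass
class CVConfig:
    """Cross-validation settings shared by the inner and outer loops."""

    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0
    rmse_rule_threshold: float = 0.05
    #: 'per_fold': mean/sd across all fold-level held-out RMSEs (the inner-CV
    #: default); 'pooled': residuals pooled within each repeat, RMSE per
    #: repeat, then mean/sd across repeats.
    aggregation: str = "per_fold"

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 <= self.rmse_rule_threshold < 1:
            raise ValueError("rmse_rule_threshold must be in [0, 1)")
        if self.aggregation not in ("per_fold", "pooled"):
            raise ValueError("aggregation must be 'per_fold' or 'pooled'")


@dataclass(frozen=True)
class CandidateCV:
    mean_rmse: float  # grams; nan when invalid
    sd_rmse: float
    valid: bool
    n_evaluations: int


@dataclass
class InnerCVResult:
    """Per-candidate mean/sd of held-out RMSE from one inner-CV pass."""

    per_candidate: dict[CandidateSpec, CandidateCV]
    threshold: float = 0.05

    def valid_candidates(self) -> list[CandidateSpec]:
        return [c for c, r in self.per_candidate.items()
                if r.valid and np.isfinite(r.mean_rmse)]


# ---------------------------------------------------------------------------
# numeric engine (operates on the raw design array; hot path of the package)
# ---------------------------------------------------------------------------

def _design_with_intercept(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    X = cohort.design_matrix().to_numpy(float)
    Z = np.column_stack([np.ones(len(X)), X])
    return Z, cohort.y


def _candidate_columns(candidates: list[CandidateSpec]) -> list[np.ndarray]:
    # column 0 is the intercept; predictor i lives at column 1 + priority index
    return [
        np.array([0] + [1 + _PRIORITY_INDEX[p] for p in c.predictors])
        for c in candidates
    ]


def _validity_mask(Z: np.ndarray, cols: list[np.ndarray]) -> np.ndarray:
    valid = np.empty(len(cols), dtype=bool)
    for i, c in enumerate(cols):
        sv = np.linalg.svd(Z[:, c], compute_uv=False)
        valid[i] = sv[-1] > 0 and sv[0] <= COND_THRESHOLD * sv[-1]
    return valid


def _solve_group(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched solve with per-candidate fallback to NaN on singular folds."""
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.full_like(b, np.nan)
        for i in range(A.shape[0]):
            try:
                out[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                logger.warning("singular fold-level design for candidate group %d", i)
        return out


def _cv_fold_errors(
    Z: np.ndarray,
    y: np.ndarray,
    cols: list[np.ndarray],
    valid: np.ndarray,
    n_folds: int,
    n_repeats: int,
    rng: np.random.Generator,
):
    """Held-out squared-error sums per candidate per fold.

    Returns (sse, counts) of shape (n_candidates, n_repeats * n_folds); NaN
    where a fold was skipped or a candidate invalid.  Fold partitions are
    exhaustive and disjoint within each repeat.
    """
    n = len(y)
    if n < n_folds:
        raise ValueError(f"cohort of size {n} cannot be split into {n_folds} folds")
    n_cand = len(cols)
    groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in sorted({len(c) for c, v in zip(cols, valid) if v}):
        members = np.array([i for i, c in enumerate(cols) if valid[i] and len(c) == k])
        groups[k] = (members, np.stack([cols[i] for i in members]))

    sse = np.full((n_cand, n_repeats * n_folds), np.nan)
    cnt = np.zeros((n_cand, n_repeats * n_folds))
    G = Z.T @ Z
    Gy = Z.T @ y
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        # canonical fold order: makes the unique leave-one-out partition
        # bit-exactly seed-invariant (summation order no longer depends on
        # the permutation)
        folds.sort(key=lambda f: int(f.min()))
        for f_idx, fold in enumerate(folds):
            col = rep * n_folds + f_idx
            m_train = n - len(fold)
            Zf = Z[fold]
            yf = y[fold]
            Gt = G - Zf.T @ Zf
            Gyt = Gy - Zf.T @ yf
            for k, (members, idx) in groups.items():
                if m_train < k + 1:
                    logger.warning("skipping fold with %d training rows (< %d params + 1)",
                                   m_train, k)
                    continue
                A = Gt[idx[:, :, None], idx[:, None, :]]
                b = Gyt[idx]
                beta = _solve_group(A, b)
                # Zf[:, idx] has shape (m, g, k): fold rows x candidates x params
                preds = np.einsum("mgk,gk->gm", Zf[:, idx], beta)
                res = yf[None, :] - preds
                sse[members, col] = np.sum(res**2, axis=1)
                cnt[members, col] = len(fold)
    return sse, cnt


def _aggregate(sse, cnt, n_folds, n_repeats, aggregation):
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # invalid candidates are all-NaN rows; their mean/sd stay NaN by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if aggregation == "per_fold":
            fold_rmse = np.sqrt(sse / cnt)
            mean = np.nanmean(fold_rmse, axis=1)
            sd = np.nanstd(fold_rmse, axis=1, ddof=1)
            n_eval = np.sum(np.isfinite(fold_rmse), axis=1)
        else:  # pooled within repeat
            sse3 = sse.reshape(sse.shape[0], n_repeats, n_folds)
            cnt3 = cnt.reshape(cnt.shape[0], n_repeats, n_folds)
            rep_rmse = np.sqrt(np.nansum(sse3, axis=2) / np.nansum(cnt3, axis=2))
            mean = np.nanmean(rep_rmse, axis=1)
            sd = np.nanstd(rep_rmse, axis=1, ddof=1) if n_repeats > 1 else np.zeros(len(sse))
            n_eval = np.sum(np.isfinite(rep_rmse), axis=1)
    return mean, sd, n_eval


def _run_inner_cv_arrays(
    Z, y, candidates: list[CandidateSpec], config: CVConfig, rng: np.random.Generator
) -> InnerCVResult:
    cols = _candidate_columns(candidates)
    valid = _validity_mask(Z, cols)
    if not valid.any():
        raise ValueError("no valid candidate (all rank-deficient)")
    sse, cnt = _cv_fold_errors(Z, y, cols, valid, config.n_folds, config.n_repeats, rng)
    mean, sd, n_eval = _aggregate(sse, cnt, config.n_folds, config.n_repeats,
                                  config.aggregation)
    per = {}
    for i, cand in enumerate(candidates):
        if valid[i]:
            per[cand] = CandidateCV(float(mean[i]), float(sd[i]), True, int(n_eval[i]))
        else:
            logger.warning("candidate %s flagged rank-deficient", cand.name)
            per[cand] = CandidateCV(float("nan"), float("nan"), False, 0)
    return InnerCVResult(per_candidate=per, threshold=config.rmse_rule_threshold)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def run_inner_cv(
    cohort: Cohort, candidates: list[CandidateSpec], config: CVConfig
) -> InnerCVResult:
    """Repeated k-fold CV of every candidate on one dataset.

    Each repeat partitions the records into ``n_folds`` random disjoint
    folds; each candidate is fitted on the complement of each fold and its
    RMSE measured on the held-out fold.  The per-candidate summary is the
    mean (and sd) of those held-out RMSEs.  Fully seeded via ``config.seed``.
    """
    Z, y = _design_with_intercept(cohort)
    rng = np.random.default_rng(config.seed)
    return _run_inner_cv_arrays(Z, y, candidates, config, rng)


def apply_parsimony_rule(
    result: InnerCVResult, threshold: float | None = None
) -> CandidateSpec:
    """Pick the candidate minimizing C = R(1 + t(N-1)), t defaulting to the
    5% rule.

    Equivalently: the best bivariable candidate displaces the best
    univariable one only when its mean CV RMSE times (1 + t) still undercuts
    the univariable RMSE.  Cost ties go to the simpler candidate, then to the
    fixed variable priority order.
    """
    t = result.threshold if threshold is None else threshold
    valid = result.valid_candidates()
    if not valid:
        raise ValueError("no valid candidates to select from")

    def key(c: CandidateSpec):
        r = result.per_candidate[c]
        cost = r.mean_rmse * (1.0 + t * (c.n_vars - 1))
        return (cost, *c.priority_key())

    return min(valid, key=key)


@dataclass
class SelectionResult:
    """Outcome of the subset-voting selection."""

    votes: dict[CandidateSpec, int]
    n_cycles: int
    winner: CandidateSpec
    cycle_winners: list[CandidateSpec] = field(default_factory=list, repr=False)

    def vote_table(self) -> list[tuple[str, int]]:
        return sorted(((c.name, v) for c, v in self.votes.items()),
                      key=lambda t: (-t[1], t[0]))


def vote_selection(
    cohort: Cohort,
    candidates: list[CandidateSpec],
    config: CVConfig,
    n_cycles: int = 100,
    subset_fraction: float = 0.9,
) -> SelectionResult:
    """Run ``n_cycles`` inner-CV selections, each on a fresh random subsample
    (without replacement, size = round(subset_fraction * n)), and collect one
    vote per cycle.  The plurality winner is returned; vote ties break toward
    fewer variables, then the fixed priority order."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not 0 < subset_fraction <= 1:
        raise ValueError("subset_fraction must be in (0, 1]")
    n = len(cohort)
    size = int(round(subset_fraction * n))
    if size < config.n_folds:
        raise ValueError(
            f"voting subset of {size} records is smaller than {config.n_folds} folds"
        )
    Z, y = _design_with_intercept(cohort)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_cycles + 1)
    subset_rng = np.random.default_rng(children[0])
    winners: list[CandidateSpec] = []
    for cycle in range(n_cycles):
        idx = subset_rng.choice(n, size=size, replace=False)
        cycle_rng = np.random.default_rng(children[cycle + 1])
        res = _run_inner_cv_arrays(Z[idx], y[idx], candidates, config, cycle_rng)
        winners.append(apply_parsimony_rule(res))
    votes = Counter(winners)
    top = max(votes.values())
    winner = min((c for c, v in votes.items() if v == top),
                 key=lambda c: c.priority_key())
    return SelectionResult(votes=dict(votes), n_cycles=n_cycles, winner=winner,
                           cycle_winners=winners)


def fit_final(cohort: Cohort, winner: CandidateSpec) -> FittedLinearModel:
    """Fit the winning candidate to the entire dataset (the final formula)."""
    return fit_ols(cohort, winner.predictors)
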