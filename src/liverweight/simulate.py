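"""Seeded synthetic donor/graft cohort generator.

Emulates an adult deceased-donor whole-liver cohort: sex is Bernoulli, height
is Gaussian within sex, weight is generated *conditionally on height* (an
allometric-like linear link) so that body weight and the two BSA estimates
are strongly collinear — the competition between bw and BSA candidates that
the selection procedure must resolve is real, not an artifact.  Graft weight
is an affine function of body weight (optionally of further predictors) plus
homoscedastic Gaussian noise.  Default marginals are calibrated to an adult
Japanese deceased-donor population (medians ~165 cm, ~60 kg, age ~46 y,
graft ~1300 g) and the default truth is the body-weight formula
14.8 x BW + 439.2 with a 200 g noise scale.

Truncations (bw > 35 kg, graft > 400 g, age within [18, 80]) exclude
physically implausible records by resampling, keeping generation exact per
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort


@dataclass
class TruthConfig:
    """Data-generating model for graft weight (grams)."""

    intercept: float = 439.2  # g
    bw_slope: float = 14.8  # g per kg
    extra_terms: dict[str, float] = field(default_factory=dict)  # predictor -> g/unit
    noise_sd: float = 200.0  # g


@dataclass
class GeneratorConfig:
    """Cohort-level generating distributions; all units as in the cohort."""

    n: int = 129
    female_prob: float = 0.434
    bh_mean_female: float = 159.0  # cm
    bh_mean_male: float = 170.0  # cm
    bh_sd: float = 6.0  # cm
    bw_given_bh_slope: float = 0.75  # kg per cm
    bw_given_bh_intercept: float = -63.0  # kg
    bw_resid_sd: float = 9.0  # kg
    bw_min: float = 35.0  # kg, truncation
    age_mean: float = 46.0  # years
    age_sd: float = 13.0
    age_bounds: tuple[float, float] = (18.0, 80.0)
    graft_min: float = 400.0  # g, truncation
    truth: TruthConfig = field(default_factory=TruthConfig)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.truth, dict):
            self.truth = TruthConfig(**self.truth)
        if not 0.0 <= self.female_prob <= 1.0:
            raise ValueError("female_prob must be in [0, 1]")
        if min(self.bh_sd, self.bw_resid_sd, self.age_sd) <= 0:
            raise ValueError("standard deviations must be positive")
        if self.truth.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n < 10:
            raise ValueError("n must be >= 10")

    def to_json(self, **kwargs) -> str:
        d = dataclasses.asdict(self)
        d["age_bounds"] = list(d["age_bounds"])
        return json.dumps(d, **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "GeneratorConfig":
        d = json.loads(s)
        if "age_bounds" in d:
            d["age_bounds"] = tuple(d["age_bounds"])
        return cls(**d)


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sampled truncated normal; deterministic per rng state."""
    mean_arr = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    out = rng.normal(mean_arr, sd)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean_arr[bad], sd)
        bad = (out < lo) | (out > hi)
    return out


def generate(config: GeneratorConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw one synthetic cohort; reproducible per (config, seed).

    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    female = rng.random(n) < config.female_prob
    bh_mean = np.where(female, config.bh_mean_female, config.bh_mean_male)
    bh = rng.normal(bh_mean, config.bh_sd)

    bw_mean = config.bw_given_bh_slope * bh + config.bw_given_bh_intercept
    bw = _truncated_normal(rng, bw_mean, config.bw_resid_sd, config.bw_min, np.inf, n)

    lo, hi = config.age_bounds
    age = _truncated_normal(rng, config.age_mean, config.age_sd, lo, hi, n)

    df = pd.DataFrame(
        {
            "donor_id": [f"SYN{i:04d}" for i in range(n)],
            "age": age,
            "sex": np.where(female, "female", "male"),
            "bw": bw,
            "bh": bh,
        }
    )
    # graft weight from the generating truth
    cohort_tmp = Cohort(df.assign(graft_weight=1000.0), validate=False)
    X = cohort_tmp.design_matrix()
    mean_y = config.truth.intercept + config.truth.bw_slope * bw
    for name, coef in config.truth.extra_terms.items():
        mean_y = mean_y + coef * X[name].to_numpy(float)
    if config.truth.noise_sd > 0:
        y = _truncated_normal(rng, mean_y, config.truth.noise_sd, config.graft_min,
                              np.inf, n)
    else:
        y = np.maximum(mean_y, config.graft_min)
    df["graft_weight"] = y
    return Cohort(df, label=f"synthetic(seed={config.seed if seed is None else seed})")


SCENARIOS = ("bw_truth", "bivariable_truth", "null_truth")


def scenario(name: str, n: int = 129, seed: int = 0) -> Cohort:
    """Named test scenarios for the selection engine.

    - ``bw_truth``: the defaults — graft weight truly depends on body weight
      only (14.8 g/kg, 439.2 g intercept, 200 g noise).
    - ``bivariable_truth``: adds an age term (-8 g/year) large enough that
      the true bivariable model's expected RMSE reduction over the best
      univariable model exceeds the 5% rule (~11% at the default age spread).
    - ``null_truth``: graft weight independent of all predictors (slope 0,
      intercept near the cohort median graft weight).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if name == "bw_truth":
        cfg = GeneratorConfig(n=n, seed=seed)
    elif name == "bivariable_truth":
        cfg = GeneratorConfig(
            n=n, seed=seed,
            truth=TruthConfig(intercept=439.2 + 8.0 * 46.0, bw_slope=14.8,
                              extra_terms={"age": -8.0}, noise_sd=200.0),
        )
    else:  # null_truth
        cfg = GeneratorConfig(
            n=n, seed=seed,
            truth=TruthConfig(intercept=1297.0, bw_slope=0.0, noise_sd=200.0),
        )
    return generate(cfg)
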