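"""Registry of previously published whole-liver weight/volume estimators.

Thirteen closed-form estimators from the transplantation literature
(1968-2010) plus the current body-weight formula, each evaluated as printed —
never refitted.  Formulas that predict liver *volume* by CT volumetry are
interpreted on the gram scale one-to-one (measured mL taken equal to g).

Sex codings differ across sources and are rarely stated; the defaults here
(Chouker: female=1, so the -166 x sex term lowers female estimates; Chan:
male=1, so the +51 x sex term raises male estimates) are assumptions,
overridable via :class:`SexCoding` and flagged in output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import Cohort
from .linear import r_squared as _r2, rmse as _rmse

logger = logging.getLogger(__name__)


@dataclass
class SexCoding:
    """Indicator conventions for the sex terms of Chouker and Chan."""

    chouker_female: int = 1  # female=1, male=0
    chan_male: int = 1  # male=1, female=0

    def chouker(self, sex: pd.Series) -> np.ndarray:
        ind = (sex == "female").to_numpy(float)
        return ind if self.chouker_female == 1 else 1.0 - ind

    def chan(self, sex: pd.Series) -> np.ndarray:
        ind = (sex == "male").to_numpy(float)
        return ind if self.chan_male == 1 else 1.0 - ind


def yuan_age_factor(age) -> np.ndarray:
    """Ordinal age coding: 1 for age <= 40, 2 for 41-60, 3 for > 60.

    (Ages exactly 40 fall in the published "<40" bin's gap; they are assigned
    factor 1.)
    """
    age = np.asarray(age, dtype=float)
    return np.where(age <= 40, 1.0, np.where(age <= 60, 2.0, 3.0))


@dataclass(frozen=True)
class PublishedFormula:
    """A named closed-form estimator with applicability constraints."""

    name: str
    year: int
    inputs: tuple[str, ...]
    output_scale: str  # 'weight_g' | 'volume_ml' (mL treated as g 1:1)
    func: Callable[[pd.DataFrame, SexCoding], np.ndarray] = field(repr=False)
    age_range: tuple[float, float] | None = None

    def evaluate(self, df: pd.DataFrame, coding: SexCoding | None = None) -> np.ndarray:
        """Predicted grams per record; caller is responsible for age_range."""
        return np.asarray(self.func(df, coding or SexCoding()), dtype=float)


def _chouker(df: pd.DataFrame, coding: SexCoding) -> np.ndarray:
    age = df["age"].to_numpy(float)
    bw = df["bw"].to_numpy(float)
    sex = coding.chouker(df["sex"])
    f1 = 452.0 + 16.34 * bw + 11.85 * age - 166.0 * sex
    f2 = 1390.0 + 15.94 * bw - 12.86 * age
    # F1 for ages 16-50; F2 for 51-70 and, by extension, above 70.
    return np.where(age <= 50, f1, f2)


def registry() -> list[PublishedFormula]:
    """The 13 published estimators plus the current formula (14 entries)."""
    F = PublishedFormula
    return [
        F("DeLand", 1968, ("bsa_dubois",), "weight_g",
          lambda d, c: 1020.0 * d["bsa_dubois"].to_numpy(float) - 220.0),
        F("Heinemann", 1999, ("bsa_dubois",), "weight_g",
          lambda d, c: 1072.8 * d["bsa_dubois"].to_numpy(float) - 345.7),
        F("Yoshizumi", 2003, ("bsa_mosteller",), "weight_g",
          lambda d, c: 772.0 * d["bsa_mosteller"].to_numpy(float)),
        F("Yu", 2004, ("bw", "bh"), "weight_g",
          lambda d, c: 21.585
          * d["bw"].to_numpy(float) ** 0.7322
          * d["bh"].to_numpy(float) ** 0.225),
        F("Chouker", 2004, ("bw", "age", "sex"), "weight_g", _chouker,
          age_range=(16.0, float("inf"))),
        F("Urata", 1995, ("bsa_dubois",), "volume_ml",
          lambda d, c: 706.2 * d["bsa_dubois"].to_numpy(float) + 2.4),
        F("Lin", 1998, ("bh", "bw"), "volume_ml",
          lambda d, c: 13.0 * d["bh"].to_numpy(float)
          + 12.0 * d["bw"].to_numpy(float) - 1530.0),
        F("Vauthey", 2002, ("bsa_mosteller",), "volume_ml",
          lambda d, c: 1267.28 * d["bsa_mosteller"].to_numpy(float) - 794.41),
        F("Hashimoto", 2006, ("bsa_mosteller",), "volume_ml",
          lambda d, c: 961.3 * d["bsa_mosteller"].to_numpy(float) - 404.8),
        F("Chan", 2006, ("bw", "sex"), "volume_ml",
          lambda d, c: 12.3 * d["bw"].to_numpy(float) + 51.0 * c.chan(d["sex"]) + 218.0),
        F("Yuan", 2008, ("bsa_dubois", "age"), "volume_ml",
          lambda d, c: 949.7 * d["bsa_dubois"].to_numpy(float)
          - 48.3 * yuan_age_factor(d["age"]) - 247.4),
        F("Fu-Gui", 2009, ("bw",), "volume_ml",
          lambda d, c: 11.508 * d["bw"].to_numpy(float) + 334.024),
        F("Poovathumkadavil", 2010, ("bw",), "volume_ml",
          lambda d, c: 12.26 * d["bw"].to_numpy(float) + 555.65),
        F("Current study", 2023, ("bw",), "weight_g",
          lambda d, c: 14.8 * d["bw"].to_numpy(float) + 439.2),
    ]


@dataclass
class FormulaEvaluation:
    """Cohort-level fit of one published formula."""

    name: str
    rmse: float  # grams
    r_squared: float
    n_evaluated: int
    n_excluded: int
    predictions: pd.Series = field(repr=False, default=None)  # grams, indexed by donor_id


def evaluate_on_cohort(
    formula: PublishedFormula, cohort: Cohort, coding: SexCoding | None = None
) -> FormulaEvaluation:
    """Evaluate a published formula against measured graft weights.

    Records outside the formula's applicability age range are excluded and
    counted; RMSE and R^2 are computed on the remaining records.
    """
    df = cohort.df
    mask = np.ones(len(df), dtype=bool)
    if formula.age_range is not None:
        lo, hi = formula.age_range
        mask = (df["age"].to_numpy(float) >= lo) & (df["age"].to_numpy(float) <= hi)
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.warning("%s: excluding %d records outside age range %s",
                       formula.name, n_excluded, formula.age_range)
    sub = df.loc[mask]
    if len(sub) == 0:
        raise ValueError(f"{formula.name}: no evaluable records")
    preds = formula.evaluate(sub, coding)
    y = sub["graft_weight"].to_numpy(float)
    return FormulaEvaluation(
        name=formula.name,
        rmse=_rmse(y, preds),
        r_squared=_r2(y, preds),
        n_evaluated=len(sub),
        n_excluded=n_excluded,
        predictions=pd.Series(preds, index=sub["donor_id"].to_numpy(), name=formula.name),
    )


def benchmark(cohort: Cohort, coding: SexCoding | None = None) -> pd.DataFrame:
    """Evaluate every registry formula; one row per formula with the accuracy
    columns (name, year, scale, n_evaluated, n_excluded, r_squared, rmse)."""
    rows = []
    for f in registry():
        ev = evaluate_on_cohort(f, cohort, coding)
        rows.append(
            {"formula": ev.name, "year": f.year, "output_scale": f.output_scale,
             "n_evaluated": ev.n_evaluated, "n_excluded": ev.n_excluded,
             "r_squared": ev.r_squared, "rmse": ev.rmse}
        )
    return pd.DataFrame(rows)
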