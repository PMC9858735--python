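"""Donor/graft cohort container, readers/writers and derived body-surface area.

A cohort is a table of deceased-donor / whole-liver-graft pairs with the five
raw fields (age, sex, body weight, body height, measured graft weight) plus
two derived body-surface-area estimates.  Units are fixed: kg, cm, years,
grams, m**2.  Measured graft *volume* in mL, where a published source reports
volume, is treated as grams one-to-one (handled in :mod:`liverweight.published`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical predictor names, in the fixed priority order used for
#: deterministic tie-breaking and design-matrix column layout.
VARIABLE_PRIORITY: tuple[str, ...] = (
    "bw",
    "bsa_dubois",
    "bsa_mosteller",
    "bh",
    "age",
    "sex",
)

RAW_FIELDS = ("age", "sex", "bw", "bh", "graft_weight")


class CohortValidationError(ValueError):
    """Raised when a cohort violates a structural invariant (missing values,
    non-positive anthropometrics, duplicate donor ids, empty table)."""


def bsa_dubois(bw, bh):
    """DuBois & DuBois body surface area, m**2.

    BSA = BW[kg]**0.425 * BH[cm]**0.725 * 0.007184
    """
    bw = np.asarray(bw, dtype=float)
    bh = np.asarray(bh, dtype=float)
    if np.any(bw <= 0) or np.any(bh <= 0):
        raise ValueError("bw and bh must be positive")
    out = bw**0.425 * bh**0.725 * 0.007184
    return float(out) if out.ndim == 0 else out


def bsa_mosteller(bw, bh):
    """Mosteller body surface area, m**2.

    BSA = sqrt(BH[cm] * BW[kg] / 3600)
    """
    bw = np.asarray(bw, dtype=float)
    bh = np.asarray(bh, dtype=float)
    if np.any(bw <= 0) or np.any(bh <= 0):
        raise ValueError("bw and bh must be positive")
    out = np.sqrt(bh * bw / 3600.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DonorRecord:
    """One donor/graft pair."""

    donor_id: str
    age: float
    sex: str  # "female" | "male"
    bw: float  # body weight, kg
    bh: float  # body height, cm
    graft_weight: float  # grams
    bsa_dubois: float  # m**2, derived
    bsa_mosteller: float  # m**2, derived


@dataclass
class ColumnMapping:
    """Maps source-file column headers onto the canonical raw fields.

    ``sex_values`` maps raw cell values (compared case-insensitively after
    ``str()``) to the canonical labels.  Numeric 0/1 encodings must be
    declared explicitly here; they are never guessed, because published
    formulas use opposite sex conventions and a silent miscode would flip
    their sex terms.
    """

    age: str = "age"
    sex: str = "sex"
    bw: str = "bw_kg"
    bh: str = "bh_cm"
    graft_weight: str = "graft_g"
    donor_id: str | None = None
    sex_values: Mapping[str, str] = field(
        default_factory=lambda: {
            "female": "female",
            "male": "male",
            "f": "female",
            "m": "male",
        }
    )

    def as_rename(self) -> dict[str, str]:
        ren = {self.age: "age", self.sex: "sex", self.bw: "bw",
               self.bh: "bh", self.graft_weight: "graft_weight"}
        if self.donor_id is not None:
            ren[self.donor_id] = "donor_id"
        return ren


class Cohort:
    """Ordered collection of donor/graft records backed by a DataFrame.

    Columns: donor_id, age, sex, bw, bh, graft_weight, bsa_dubois,
    bsa_mosteller.  BSAs are (re)derived from bw/bh on construction.
    """

    COLUMNS = ("donor_id", "age", "sex", "bw", "bh", "graft_weight",
               "bsa_dubois", "bsa_mosteller")

    def __init__(self, df: pd.DataFrame, label: str = "", validate: bool = True):
        df = df.copy().reset_index(drop=True)
        if "donor_id" not in df.columns:
            df["donor_id"] = [f"D{i:04d}" for i in range(len(df))]
        df["donor_id"] = df["donor_id"].astype(str)
        for col in ("age", "bw", "bh", "graft_weight"):
            df[col] = pd.to_numeric(df[col])
        if (df["bw"] <= 0).any() or (df["bh"] <= 0).any():
            raise CohortValidationError("bw and bh must be positive")
        df["bsa_dubois"] = bsa_dubois(df["bw"].to_numpy(), df["bh"].to_numpy())
        df["bsa_mosteller"] = bsa_mosteller(df["bw"].to_numpy(), df["bh"].to_numpy())
        self._df = df[list(self.COLUMNS)]
        self.label = label
        self.exclusions: pd.DataFrame | None = None  # set by read_cohort
        if validate:
            self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def records(self) -> Iterator[DonorRecord]:
        for row in self._df.itertuples(index=False):
            yield DonorRecord(*row)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "Cohort":
        return cls(df, label=label)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self._df
        if len(df) == 0:
            raise CohortValidationError("empty cohort")
        if df["donor_id"].duplicated().any():
            dupes = df.loc[df["donor_id"].duplicated(), "donor_id"].tolist()
            raise CohortValidationError(f"duplicate donor ids: {dupes}")
        for col in ("age", "sex", "graft_weight"):
            if df[col].isna().any():
                raise CohortValidationError(f"missing values in required field {col!r}")
        bad_sex = ~df["sex"].isin(["female", "male"])
        if bad_sex.any():
            raise CohortValidationError(
                f"sex must be 'female' or 'male'; got {sorted(df.loc[bad_sex, 'sex'].unique())}"
            )
        for col, lo in (("bw", 0.0), ("bh", 0.0), ("graft_weight", 0.0)):
            if (df[col] <= lo).any() or df[col].isna().any():
                raise CohortValidationError(f"{col} must be positive and non-missing")
        if (df["age"] < 0).any():
            raise CohortValidationError("age must be >= 0")

    # -- numeric views ------------------------------------------------------
    def design_matrix(self) -> pd.DataFrame:
        """Predictor matrix in VARIABLE_PRIORITY column order.

        Sex enters as an indicator with female=1, male=0.
        """
        df = self._df
        out = pd.DataFrame(
            {
                "bw": df["bw"].to_numpy(float),
                "bsa_dubois": df["bsa_dubois"].to_numpy(float),
                "bsa_mosteller": df["bsa_mosteller"].to_numpy(float),
                "bh": df["bh"].to_numpy(float),
                "age": df["age"].to_numpy(float),
                "sex": (df["sex"] == "female").to_numpy(float),
            }
        )
        return out[list(VARIABLE_PRIORITY)]

    @property
    def y(self) -> np.ndarray:
        return self._df["graft_weight"].to_numpy(float)

    # -- output -------------------------------------------------------------
    def write_delimited(self, path, sep: str = ",") -> None:
        """Write the cohort as delimited text.

        Floats are written with 17 significant digits; a write/read cycle
        reproduces every field bit-exactly.
        """
        self._df.to_csv(path, sep=sep, index=False, float_format="%.17g")

    def subset(self, indices) -> "Cohort":
        sub = Cohort(self._df.iloc[np.asarray(indices)], label=self.label, validate=False)
        return sub


@dataclass
class CohortSummary:
    """Median/IQR table in the style of a baseline-characteristics table."""

    n: int
    female_prevalence: float
    variables: dict[str, tuple[float, float, float]]  # var -> (q1, median, q3)

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Medians with interquartile ranges (type-7 linear-interpolation
    quantiles) for the continuous variables, prevalence for sex."""
    df = cohort.df
    if len(df) == 0:
        raise CohortValidationError("empty cohort")
    variables = {}
    for col in ("age", "bh", "bw", "bsa_dubois", "bsa_mosteller", "graft_weight"):
        q1, med, q3 = np.quantile(df[col].to_numpy(float), [0.25, 0.5, 0.75])
        variables[col] = (float(q1), float(med), float(q3))
    return CohortSummary(
        n=len(df),
        female_prevalence=float((df["sex"] == "female").mean()),
        variables=variables,
    )


def _canonical_sex(series: pd.Series, sex_values: Mapping[str, str]) -> pd.Series:
    lut = {str(k).strip().lower(): v for k, v in sex_values.items()}

    def conv(v):
        if pd.isna(v):
            return np.nan
        key = str(v).strip().lower()
        # "1.0" from spreadsheets declared as "1"
        if key.endswith(".0") and key[:-2] in lut:
            key = key[:-2]
        return lut.get(key, np.nan)

    return series.map(conv)


def _sniff_delimiter(source) -> str:
    """Comma unless the header looks tab-separated."""
    if hasattr(source, "read"):
        head = source.readline()
        source.seek(0)
    else:
        with open(source, "r") as fh:
            head = fh.readline()
    return "\t" if "\t" in head else ","


def read_cohort(
    source,
    format: str = "delimited",
    mapping: ColumnMapping | None = None,
    sep: str | None = None,
    label: str | None = None,
) -> Cohort:
    """Read a cohort from delimited text or a spreadsheet (first sheet).

    Rows with any missing raw field, non-positive anthropometrics, or an
    unmappable sex value are excluded; they are logged and attached to the
    returned cohort as ``cohort.exclusions`` (with a ``reason`` column).

    Raises ``CohortValidationError`` if no mappable columns or no valid rows
    remain.
    """
    mapping = mapping or ColumnMapping()
    if format == "delimited":
        if sep is None:
            sep = _sniff_delimiter(source)
        # round_trip parsing so write/read cycles are bit-exact
        raw = pd.read_csv(source, sep=sep, float_precision="round_trip")
    elif format == "spreadsheet":
        raw = pd.read_excel(source, sheet_name=0)
    else:
        raise ValueError(f"unknown format {format!r}")

    raw.columns = [str(c).strip() for c in raw.columns]
    rename = mapping.as_rename()
    present = [c for c in rename if c in raw.columns]
    missing_cols = [c for c, canon in rename.items()
                    if c not in raw.columns and canon != "donor_id"]
    if missing_cols:
        # allow canonical headers as a fallback before giving up
        canon_ok = all(rename[c] in raw.columns for c in missing_cols)
        if not canon_ok:
            raise CohortValidationError(
                f"cannot map required columns {missing_cols}; found {list(raw.columns)}"
            )
    df = raw.rename(columns={c: rename[c] for c in present})

    for col in ("age", "bw", "bh", "graft_weight"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["sex"] = _canonical_sex(df["sex"], mapping.sex_values)

    reasons = pd.Series("", index=df.index, dtype=object)
    for col in RAW_FIELDS:
        bad = df[col].isna()
        reasons[bad] = reasons[bad] + f"missing/invalid {col};"
    for col in ("bw", "bh", "graft_weight"):
        bad = df[col].notna() & (df[col] <= 0)
        reasons[bad] = reasons[bad] + f"non-positive {col};"
    excluded = reasons != ""
    if excluded.any():
        logger.warning("read_cohort: excluding %d of %d rows", int(excluded.sum()), len(df))
    kept = df.loc[~excluded]
    if len(kept) == 0:
        raise CohortValidationError("no valid records after exclusions")
    cohort = Cohort(
        kept[[c for c in ("donor_id", *RAW_FIELDS) if c in kept.columns]],
        label=label or str(source),
    )
    report = raw.loc[excluded].copy()
    report["reason"] = reasons[excluded]
    cohort.exclusions = report
    return cohort
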