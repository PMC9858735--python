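import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import liverweight as lw

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bw_cohort() -> lw.Cohort:
    """One default synthetic cohort: graft weight = 439.2 + 14.8*bw + N(0,200)."""
    return lw.scenario("bw_truth", seed=1)


@pytest.fixture(scope="session")
def exact_cohort() -> lw.Cohort:
    """Noiseless cohort: graft weight exactly 439.2 + 14.8*bw."""
    return lw.generate(lw.GeneratorConfig(seed=7, truth=lw.TruthConfig(noise_sd=0.0)))


@pytest.fixture(scope="session")
def fixture_donors() -> pd.DataFrame:
    """Three hand-checkable donors spanning the formulas' branches."""
    df = pd.DataFrame(
        {
            "donor_id": ["A", "B", "C"],
            "age": [35.0, 55.0, 65.0],
            "sex": ["female", "male", "male"],
            "bw": [50.0, 70.0, 80.0],
            "bh": [155.0, 172.0, 168.0],
            "graft_weight": [1100.0, 1500.0, 1600.0],
        }
    )
    return df


@pytest.fixture(scope="session")
def fixture_cohort(fixture_donors) -> lw.Cohort:
    return lw.Cohort.from_dataframe(fixture_donors, label="fixture")


def make_cohort(bw, bh=None, age=None, sex=None, y=None) -> lw.Cohort:
    """Small ad-hoc cohort builder for arithmetic tests."""
    bw = np.asarray(bw, dtype=float)
    n = len(bw)
    df = pd.DataFrame(
        {
            "age": np.full(n, 40.0) if age is None else np.asarray(age, float),
            "sex": ["male"] * n if sex is None else sex,
            "bw": bw,
            "bh": np.full(n, 170.0) if bh is None else np.asarray(bh, float),
            "graft_weight": 2.0 * bw if y is None else np.asarray(y, float),
        }
    )
    return lw.Cohort.from_dataframe(df)
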