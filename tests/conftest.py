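"""Shared fixtures: small synthetic cohorts and toy datasets."""

import numpy as np
import pandas as pd
import pytest

from likingdqi.cohort import CohortSpec, generate_cohort
from likingdqi.survey import GroupSchema
from likingdqi.validation import Dataset


@pytest.fixture(scope="session")
def schema() -> GroupSchema:
    return GroupSchema.default()


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate default-condition cohort reused across read-only tests."""
    return generate_cohort(CohortSpec(n=800, seed=7))


@pytest.fixture(scope="session")
def default_dataset(default_cohort) -> Dataset:
    return Dataset.from_cohort(default_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_biomarker_frame(n: int, seed: int) -> pd.DataFrame:
    """Unstructured but physiologically plausible biomarker table."""
    r = np.random.default_rng(seed)
    return pd.DataFrame({
        "insulin": np.exp(r.normal(2.4, 0.5, n)),
        "glucose": r.normal(89, 8, n).clip(50),
        "hdl": r.normal(58, 12, n).clip(20),
        "ldl": r.normal(91, 25, n).clip(20),
        "total_cholesterol": r.normal(168, 30, n).clip(80),
        "triglycerides": np.exp(r.normal(4.5, 0.45, n)),
        "bmi": np.exp(r.normal(3.2, 0.2, n)),
        "whr": r.normal(0.82, 0.07, n).clip(0.5, 1.5),
        "sbp": r.normal(111, 13, n).clip(80),
        "dbp": r.normal(72, 9, n).clip(45),
    }, index=[f"S{i:05d}" for i in range(n)])
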