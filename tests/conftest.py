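import numpy as np
import pandas as pd
import pytest

from homacut import GeneratorConfig, compute_homa_ir, generate_cohort


def make_subject(**overrides) -> dict:
    """A metabolically unremarkable subject; fields overridable per test."""
    base = {
        "id": "S00000",
        "sex": "M",
        "age": 10.0,
        "tanner": 2,
        "height_cm": 140.0,
        "weight_kg": 35.0,
        "bmi": 35.0 / 1.4**2,
        "wc_cm": 60.0,
        "fat_pct": 20.0,
        "sbp": 100.0,
        "dbp": 62.0,
        "tc": 4.0,
        "tg": 0.8,
        "hdl": 1.5,
        "ldl": 2.4,
        "glucose": 4.8,
        "insulin": 6.0,
    }
    base.update(overrides)
    return base


def make_cohort_frame(subjects) -> pd.DataFrame:
    df = pd.DataFrame(subjects)
    df["id"] = [f"S{i:05d}" for i in range(len(df))]
    return df


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    cohort = generate_cohort(GeneratorConfig(seed=20))
    df = cohort.data.copy()
    df["homa_ir"] = compute_homa_ir(df["insulin"], df["glucose"])
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
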