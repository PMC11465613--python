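import numpy as np
import pandas as pd
import pytest

from diabrisk.cohort import VISIT_COLUMNS
from diabrisk.simulate import SimConfig, generate_cohort

_DEFAULT_VISIT = {
    "participant_id": "P1",
    "visit_index": 1,
    "age": 50.0,
    "sex": "female",
    "waist_circumference": 85.0,
    "bmi": 26.0,
    "systolic_bp": 125.0,
    "diastolic_bp": 80.0,
    "bp_medication": "no",
    "hypertension": "no",
    "family_history_dm": "no",
    "physical_activity": 2.0,
    "residency": "rural",
    "diabetes_medication": "no",
    "fpg": 5.5,
    "hba1c": 5.6,
}


def visit(**overrides) -> dict:
    """One visit row with sensible defaults, overridable per field."""
    row = dict(_DEFAULT_VISIT)
    row.update(overrides)
    return row


def visit_table(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in VISIT_COLUMNS:
        if col not in df.columns:
            df[col] = _DEFAULT_VISIT[col]
    return df[VISIT_COLUMNS]


@pytest.fixture
def make_visit():
    return visit


@pytest.fixture
def make_table():
    return visit_table


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic cohort (937 participants, seed 42) plus its true model."""
    return generate_cohort(SimConfig(), seed=42)


@pytest.fixture
def rng(request):
    # stable per-test stream: independent of execution order and hash seed
    import zlib

    seed = zlib.crc32(request.node.name.encode()) % (2**31)
    return np.random.default_rng(seed)
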