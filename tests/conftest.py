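import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import obsact as oa
from obsact.simulate import TRIAL_COLUMNS

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def exp1_spec():
    return oa.make_experiment_spec("exp1_rsg_g15")


@pytest.fixture(scope="session")
def exp3_spec():
    return oa.make_experiment_spec("exp3_reach_rot60")


@pytest.fixture(scope="session")
def interval_prior():
    """11-point discrete uniform prior on [600, 1000] ms."""
    return oa.PriorSpec(600.0, 1000.0, "discrete_uniform", 11)


@pytest.fixture(scope="session")
def late_observer():
    return oa.ObserverParams(
        "late", oa.NoiseModel("scalar", 0.12), oa.NoiseModel("scalar", 0.07)
    )


@pytest.fixture(scope="session")
def late_interval_table(exp1_spec, late_observer):
    """One session of a late-inference observer in the identity timing context."""
    return oa.generate_subject(exp1_spec, "identity", late_observer, 600, seed=123)


def make_cell_table(cells, context="identity", units="ms"):
    """Build a trial table from {correct: [produced, ...]} cell specs.

    Samples equal the correct values (identity context), which is all the
    summary statistics need.
    """
    rows = []
    trial = 1
    for correct, produced in cells.items():
        for p in produced:
            rows.append(
                {
                    "subject_id": "T01",
                    "session": 1,
                    "block": 1,
                    "trial": trial,
                    "context": context,
                    "sample": float(correct),
                    "correct": float(correct),
                    "produced": float(p),
                    "units": units,
                    "excluded_reason": pd.NA,
                }
            )
            trial += 1
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["excluded_reason"] = df["excluded_reason"].astype("string")
    return df


@pytest.fixture
def cell_table_factory():
    return make_cell_table
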