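import numpy as np
import pandas as pd
import pytest

from survsig.io_formats import ExpressionMatrix, SurvivalTable
from survsig.synthetic import CohortSpec, simulate_cohort


def make_survival(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame({"sample_id": ids, "time_days": times, "event": events})
    )


def random_survival(rng, n, max_time=10, censor_p=0.3):
    """Small random right-censored dataset with integer (tie-prone) times."""
    times = rng.integers(1, max_time, size=n).astype(float)
    events = (rng.random(n) > censor_p).astype(int)
    if events.sum() == 0:
        events[rng.integers(0, n)] = 1
    return make_survival(times, events)


@pytest.fixture
def four_events():
    """Times 1..4, all events; the closed-form Cox example dataset."""
    return make_survival([1, 2, 3, 4], [1, 1, 1, 1])


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate synthetic cohort shared across read-only tests."""
    spec = CohortSpec(
        n_samples=300,
        n_genes=200,
        n_risk_genes=10,
        n_diff_mut_genes=15,
        hazard_beta=1.2,
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture
def tiny_expression():
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=["TP53", "BRCA1"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(frame, unit_tag="fpkm")
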