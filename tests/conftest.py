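import numpy as np
import pandas as pd
import pytest

from dietconn import simstudy
from dietconn.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def fast_cohort():
    """Default-size fast-mode cohort with the printed missingness cascade."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def analytic():
    """Analytic table from one fast-mode cohort of 201 (no missingness)."""
    return simstudy.simulate_analytic(simstudy.make_config("tab2-stratified", seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_participants(n=40, seed=0):
    """Small hand-rollable participant table with valid covariates."""
    r = np.random.default_rng(seed)
    races = np.array(["non-Hispanic white", "non-Hispanic black", "other"])
    return pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "age": r.uniform(20, 80, n),
            "female": r.integers(0, 2, n),
            "race": races[r.integers(0, 3, n)],
            "education": r.uniform(12, 22, n),
            "nart_iq": r.uniform(95, 130, n),
            "caloric_intake": r.uniform(1200, 2600, n),
            "cortical_thickness": r.uniform(2.3, 2.8, n),
            "brain_volume": r.normal(0, 5e4, n),
            "wmh": r.uniform(0, 5000, n),
            "fa": r.uniform(0.40, 0.48, n),
            "scrub_pct": r.uniform(0, 20, n),
        }
    )
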