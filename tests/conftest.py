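import numpy as np
import pandas as pd
import pytest

from opioidcf import cohort_synth as cs
from opioidcf import pkpd


@pytest.fixture(scope="session")
def one_compartment_params():
    """Degenerate parameters with a closed-form solution (k12 = k13 = 0)."""
    return pkpd.PKModelParameters(
        drug="drugA", V1=10.0, k10=0.05, k12=0.0, k21=0.0, k13=0.0, k31=0.0,
        ke0=0.2, n_compartments=3,
    )


@pytest.fixture(scope="session")
def three_compartment_params():
    return pkpd.PKModelParameters(
        drug="drugA", V1=12.0, k10=0.06, k12=0.25, k21=0.12, k13=0.1, k31=0.004,
        ke0=0.15, n_compartments=3,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-patient default-condition synthetic cohort, shared across tests."""
    return cs.generate_cohort(cs.default_config(2000, pk_dt=1.0), seed=20260901)


@pytest.fixture(scope="session")
def large_cohort():
    """A 20000-patient cohort for coefficient-recovery checks."""
    return cs.generate_cohort(cs.default_config(20000, pk_dt=2.0), seed=20260902)


@pytest.fixture(scope="session")
def logistic_fixture_200():
    """A 200-row fixed design + binary outcome for reference cross-checks."""
    rng = np.random.default_rng(7)
    n = 200
    df = pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.binomial(1, 0.4, n).astype(float),
        }
    )
    eta = 0.3 + 0.8 * df.x1 - 0.6 * df.x2
    df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return df
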