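import numpy as np
import pandas as pd
import pytest

from coldtme import ExpressionTable, Space
from coldtme.simulate import simulate_cohort, simulate_integration_study


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort simulation."""
    return simulate_cohort(
        n_samples=80,
        n_genes=200,
        leukocyte_set_size=8,
        nrf2_set_size=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def integration_study():
    return simulate_integration_study(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_linear_table(rng, n_genes=12, n_samples=4) -> ExpressionTable:
    genes = [f"g{i:02d}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    vals = rng.gamma(2.0, 50.0, size=(n_genes, n_samples))
    return ExpressionTable(
        values=pd.DataFrame(vals, index=genes, columns=samples), space=Space.linear
    )
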