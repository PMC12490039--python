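import numpy as np
import pandas as pd
import pytest

from coexnet.containers import ExpressionMatrix
from coexnet.simulate import SimulationConfig, default_config, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Three planted modules at desk size; quick to simulate and cluster."""
    return SimulationConfig(
        n_genes=200,
        module_sizes=(50, 40, 30),
        n_samples_per_condition=(12, 14),
        factor_dag=((1, 2, 0.6),),
        condition_shift=((1, 2.0),),
        n_tfs=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference study-scale conditions: 1000 genes, 5 modules, 16+27."""
    return simulate_dataset(default_config(seed=0))


@pytest.fixture()
def toy_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.normal(size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(8)],
    )
    condition = pd.Series(["A"] * 4 + ["B"] * 4, index=values.columns)
    return ExpressionMatrix(values, condition)
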