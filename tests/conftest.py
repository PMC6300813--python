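import numpy as np
import pandas as pd
import pytest

from cofuncnet.cofunc import run_pipeline
from cofuncnet.io import EffectMatrix
from cofuncnet.simulate import SimulationConfig, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """20 genes x 12 cell lines of plain Gaussian effects."""
    genes = [f"G{i:02d}" for i in range(20)]
    cells = [f"ACH-{i:06d}" for i in range(12)]
    return EffectMatrix(pd.DataFrame(rng.standard_normal((20, 12)), index=genes, columns=cells))


@pytest.fixture(scope="session")
def default_sim():
    """Standard study conditions: 1,000 genes / 250 controls / 200 cells,
    two unit-strength confounders, ten 10-gene modules at effect 0.8."""
    return simulate_screen(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def called_pipeline(default_sim):
    """Corrected pipeline run on the standard synthetic screen."""
    matrix, truth = default_sim
    return run_pipeline(matrix, truth.controls, seed=11)
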