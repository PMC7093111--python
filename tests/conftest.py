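import numpy as np
import pandas as pd
import pytest

from regenddr import SimulationConfig, TimecourseExpressionSet


@pytest.fixture
def small_expr() -> TimecourseExpressionSet:
    """Three genes, four timepoints: one up, one down, one flat."""
    values = pd.DataFrame(
        {
            0: [10.0, 8.0, 5.0],
            3: [25.0, 8.5, 5.2],
            7: [30.0, 3.0, 4.9],
            14: [12.0, 7.0, 5.0],
        },
        index=["upg", "downg", "flatg"],
    )
    return TimecourseExpressionSet(values)


@pytest.fixture
def zero_noise_config() -> SimulationConfig:
    return SimulationConfig(seed=1, n_genes=200, noise_cv=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
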