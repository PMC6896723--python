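import numpy as np
import pandas as pd
import pytest

from ffpe_concordance import (
    ExpressionMatrix,
    SimulationConfig,
    StudyDesign,
    make_design,
    simulate_study,
)


@pytest.fixture
def paper_shaped_design() -> StudyDesign:
    """12 cancers x (FF + 3 kits) with duplicate extractions everywhere."""
    return make_design(
        [f"C{i:02d}" for i in range(1, 13)],
        ["FF", "N", "Q", "R"],
        {"FF": 2, "N": 2, "Q": 2, "R": 2},
    )


@pytest.fixture
def small_study():
    """A modest simulated study with every variance component active."""
    config = SimulationConfig(n_genes=120, n_reference_genes=8, seed=42)
    matrix, design, truth = simulate_study(config)
    return config, matrix, design, truth


@pytest.fixture
def zero_noise_study():
    """Deterministic limit: all random components switched off."""
    config = SimulationConfig(
        n_genes=40,
        n_reference_genes=5,
        seed=7,
        sigma_cancer=0.0,
        kit_bias=0.3,
        kit_bias_sd=0.0,
        slope_sd=0.0,
        replicate_sd=0.0,
    )
    matrix, design, truth = simulate_study(config)
    return config, matrix, design, truth


def toy_matrix(values, genes=None, samples=None, scale="log2") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)
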