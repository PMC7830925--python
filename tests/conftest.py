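import numpy as np
import pandas as pd
import pytest

from fibroprog.diffexpr import ExpressionStudy
from fibroprog.simulate import SimulationConfig, simulate_studies, toy_metabolic_model


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_models=3, genes=400, common_up=20, common_down=5,
        specific_per_model=10, decoy_set_count=10, seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_studies(small_config)


@pytest.fixture(scope="session")
def toy_model():
    """The shipped network with its placeholder gene names."""
    return toy_metabolic_model()


@pytest.fixture()
def tiny_study() -> ExpressionStudy:
    """Three genes, three samples per group, hand-enterable numbers."""
    mat = pd.DataFrame(
        {
            "w1": [1.0, 5.0, 0.0],
            "w2": [2.0, 5.0, 0.0],
            "w3": [3.0, 5.0, 0.0],
            "k1": [2.0, 5.0, 1.0],
            "k2": [3.0, 5.0, 1.0],
            "k3": [4.0, 5.0, 1.0],
        },
        index=["gA", "gB", "gC"],
    )
    group = pd.Series(
        ["WT", "WT", "WT", "KO", "KO", "KO"], index=mat.columns
    )
    return ExpressionStudy(matrix=mat, group=group, model_label="tiny")


def make_null_study(
    n_genes: int, n_per_group: int, seed: int, sigma2: float | np.ndarray = 0.04
) -> ExpressionStudy:
    rng = np.random.default_rng(seed)
    sigma = np.broadcast_to(np.sqrt(sigma2), (n_genes,))
    mat = rng.normal(0, sigma[:, None], size=(n_genes, 2 * n_per_group))
    cols = [f"w{i}" for i in range(n_per_group)] + [f"k{i}" for i in range(n_per_group)]
    frame = pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    group = pd.Series(["WT"] * n_per_group + ["KO"] * n_per_group, index=cols)
    return ExpressionStudy(matrix=frame, group=group, model_label="null")
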