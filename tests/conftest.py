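import numpy as np
import pandas as pd
import pytest

from immunosig.panels import GenePanel, PanelRegistry, default_registry
from immunosig.preprocess import ExpressionMatrix
from immunosig.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def registry() -> PanelRegistry:
    return default_registry()


@pytest.fixture(scope="session")
def small_panel() -> GenePanel:
    return GenePanel(name="toy", genes=tuple(f"G{i:03d}" for i in range(1, 41)), source="test")


@pytest.fixture(scope="session")
def strong_cohort(small_panel):
    """Well-separated 4-cluster cohort: gradient (0,1,2,3), low noise."""
    cfg = SyntheticConfig(
        cluster_sizes=(10, 10, 10, 10),
        n_background_genes=60,
        responsive_fraction=0.5,
        gradient=(0.0, 1.0, 2.0, 3.0),
        noise_sd=0.3,
        seed=11,
    )
    return generate_cohort(cfg, small_panel)


@pytest.fixture()
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.uniform(0.5, 12, size=(15, 9)),
        index=[f"G{i}" for i in range(15)],
        columns=[f"S{i}" for i in range(9)],
    )
    return ExpressionMatrix(data=data, scale="log2")
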