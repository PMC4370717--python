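import numpy as np
import pandas as pd
import pytest

from agribirds.synthetic_data import (
    ScenarioConfig,
    generate_counts,
    generate_covariates,
    generate_landscape,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully structured scenario: 20 SARs, 30 sites."""
    return ScenarioConfig(seed=11, rows=4, cols=5, n_sites=30)


@pytest.fixture(scope="session")
def small_landscape(small_cfg):
    return generate_landscape(small_cfg)


@pytest.fixture(scope="session")
def small_tables(small_cfg, small_landscape):
    """Full input bundle for the small scenario."""
    cov = generate_covariates(small_cfg, small_landscape)
    return dict(
        counts=generate_counts(small_cfg, small_landscape),
        farms=small_landscape.farms,
        edges=pd.DataFrame(small_landscape.edges, columns=["unit_a", "unit_b"]),
        **cov,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
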