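import numpy as np
import pandas as pd
import pytest

from pinemort.synthetic import StemMapSpec, SyntheticConfig, generate_landscape, generate_stem_map


@pytest.fixture(scope="session")
def small_landscape():
    """4 sites x ~30 cells with the default effect sizes."""
    cfg = SyntheticConfig(n_sites=4, cells_per_site=30, grid_side_cells=6, seed=101)
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def stem_map():
    return generate_stem_map(StemMapSpec(extent_m=(100.0, 100.0), density=400.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_stem_map(rng, n, extent=50.0):
    return pd.DataFrame(
        {
            "x_m": rng.uniform(0, extent, n),
            "y_m": rng.uniform(0, extent, n),
            "height_m": rng.uniform(2, 40, n),
        }
    )
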