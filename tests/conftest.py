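import numpy as np
import pandas as pd
import pytest

from soxtarget import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic dataset at the default configuration."""
    return simulate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_counts():
    """Hand-written count table with a reference and a marker gene."""
    return pd.DataFrame(
        {
            "gene_id": ["Actb", "Col2a1", "geneA", "geneB", "geneC"],
            "tags_control": [1000, 158_000, 800, 101, 100],
            "tags_treated": [1000, 80_000, 100, 404, 100],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
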