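import numpy as np
import pytest

from popshift import synthetic
from popshift.io import ExpressionMatrix


@pytest.fixture(scope="session")
def compendium_seed1():
    """Default synthetic compendium (2000 genes x 200 strains, seed 1)."""
    return synthetic.make_compendium(seed=1)


@pytest.fixture(scope="session")
def cycle_series_seed7():
    """Default noiseless synthetic cycle series, seed 7."""
    series, truth = synthetic.make_cycle_series(seed=7)
    return series, truth


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(42)
    vals = rng.normal(size=(6, 4))
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=[f"s{j}" for j in range(4)],
        values=vals,
    )
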