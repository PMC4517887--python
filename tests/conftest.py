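import numpy as np
import pytest

from pathrank import (
    build_global_network,
    compute_similarities,
    toy_fixture,
)


@pytest.fixture(scope="session")
def toy():
    """Hand-written 7-gene / 3-sample study."""
    datasets, prior, compendium = toy_fixture()
    return datasets, prior, compendium


@pytest.fixture(scope="session")
def toy_global(toy):
    datasets, prior, _ = toy
    return build_global_network(datasets, prior, merge_expression=False)


@pytest.fixture(scope="session")
def toy_global_merged(toy):
    datasets, prior, _ = toy
    return build_global_network(datasets, prior, merge_expression=True)


@pytest.fixture(scope="session")
def toy_submatrices(toy_global):
    return compute_similarities(toy_global, alpha=0.01)


@pytest.fixture(scope="session")
def toy_submatrices_merged(toy_global_merged):
    return compute_similarities(toy_global_merged, alpha=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
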