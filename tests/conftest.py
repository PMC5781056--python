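import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import succpred as sp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_synthetic():
    """A small balanced synthetic study set shared across tests."""
    config = sp.SyntheticConfig(
        n_proteins=8,
        length_range=(250, 350),
        n_pos=25,
        n_neg=25,
        effect_size=0.5,
        seed=42,
    )
    return sp.generate(config)


@pytest.fixture(scope="session")
def small_dataset(small_synthetic):
    d = small_synthetic
    return sp.build_dataset(d.records, d.pssms, d.profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_tree(small_synthetic, tmp_path_factory):
    """The small synthetic set written as on-disk files."""
    directory = tmp_path_factory.mktemp("fixture_tree")
    paths = sp.write_fixture_set(small_synthetic, directory)
    return paths
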