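import pytest

from vocalstyle import SimConfig, simulate_study, write_bundle


@pytest.fixture(scope="session")
def small_config():
    """A small but complete study: 5 species, 2 groups each, 5-7 members."""
    return SimConfig(n_species=5, groups_per_species=(2, 2),
                     individuals_per_group=(5, 7),
                     tau=[-0.8, -0.2, 0.3, 0.6, 0.9], seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    write_bundle(small_bundle, out)
    return out
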