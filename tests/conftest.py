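import pytest

from cazymag.simulate import SyntheticConfig, write_fixture_bundle


@pytest.fixture(scope="session")
def small_config():
    """A small community with every kind of planted structure."""
    return SyntheticConfig(
        seed=42,
        n_phyla=3,
        mags_per_phylum=15,
        family_pool_size=40,
        n_differential=5,
        host_effect_r=0.5,
        gd_abundance_rho=0.5,
        correlated_phyla=("PhylumA",),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    """The small community written out as a fixture-bundle directory."""
    directory = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_config, directory)
    return directory
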