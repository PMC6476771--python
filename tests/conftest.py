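import pytest

from fruitniche import GeneratorConfig, generate, make_toy_fixture


@pytest.fixture(scope="session")
def toy():
    """Tiny hand-computed dataset and its expected outputs."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down generator config for fast unit tests."""
    return GeneratorConfig(
        seed=42,
        n_taxa=8,
        n_transects=5,
        points_per_transect=40,
        n_plots=40,
        phenology_individuals=6,
        samples_per_month=10,
        nests_per_season=120,
        n_fallback=2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)
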