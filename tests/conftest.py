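import warnings

import pytest

from icebrass import SyntheticConfig, generate_population, harmonize
from icebrass.survey import derive_fields, exclude_pregnant


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_per_wave={2000: 1200, 2015: 1500},
        n_clusters=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def population(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def harmonized(population):
    """Derived + pregnancy-filtered two-wave analysis table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return exclude_pregnant(derive_fields(population))


@pytest.fixture(scope="session")
def harmonized_with_gps(small_config, population):
    from icebrass import generate_gps

    waves = [g.reset_index(drop=True) for _, g in population.groupby("wave_year")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, log = harmonize(waves, gps=generate_gps(small_config))
    return table, log
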