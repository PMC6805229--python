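import dataclasses

import pytest

from diatom_ntrans import abundance
from diatom_ntrans.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A reduced sampling design: 20 stations, DCM at half of them."""
    return ScenarioConfig(n_stations=20, dcm_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def default_scenario():
    """The full default design (65 stations, 42 with DCM)."""
    return generate_scenario(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def occurrence_tables(small_scenario):
    env, mrna, dna, ko, truth = small_scenario
    occ_m = abundance.normalize_occurrence(mrna, "mrna_occurrence")
    occ_d = abundance.normalize_occurrence(dna, "dna_occurrence")
    return occ_m, occ_d


def config_with(base: ScenarioConfig, **kw) -> ScenarioConfig:
    return dataclasses.replace(base, **kw)
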