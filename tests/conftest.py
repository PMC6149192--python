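import pytest

from pdxkit import simulate as sim
from pdxkit.config import SimulationConfig


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def reference_pair(default_config):
    return sim.gen_reference_pair(default_config)


@pytest.fixture(scope="session")
def labeled_reads(default_config, reference_pair):
    return sim.gen_reads(default_config, reference_pair)


@pytest.fixture(scope="session")
def gene_models(default_config):
    return sim.gen_gene_models(default_config)
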