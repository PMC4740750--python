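import pytest

from spfid.synthetic_data import PrecursorSet, SimConfig, generate_precursors


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def precursor_set(sim_config) -> PrecursorSet:
    return generate_precursors(sim_config)
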