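import pytest

import riverwq as wq


@pytest.fixture(scope="session")
def standards():
    return wq.load_standards()


@pytest.fixture(scope="session")
def pre_means():
    return wq.phase_means("pre_lockdown")


@pytest.fixture(scope="session")
def lockdown_means():
    return wq.phase_means("lockdown")


@pytest.fixture(scope="session")
def unlock_means():
    return wq.phase_means("unlock")


@pytest.fixture()
def campaign(standards):
    """A small deterministic synthetic campaign (11 sites × 3 phases)."""
    records = wq.generate(wq.SyntheticSpec(seed=20))
    return wq.validate_samples(records, standards)
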