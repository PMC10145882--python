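import pytest

from ethoflow.catalogue import sequence_from_tokens
from ethoflow.simulate import aei_profile, rei_profile, simulate_batch

# Canonical single-long mating chain (the flow-ethogram backbone): courtship
# with one loop pass, copulation, and the full postcopulatory tail.
CANONICAL_L_TOKENS = [
    "pounce", "sound", "ant", "buzz", "ant", "abdom", "back", "rot",
    "long", "ant", "end_cop", "scratch", "ant", "inact", "ant",
    "groom", "bye_bye",
]


@pytest.fixture
def canonical_l_sequence():
    return sequence_from_tokens(CANONICAL_L_TOKENS, subject_id="canonical-L")


@pytest.fixture(scope="session")
def rei_batch():
    """Moderate REI batch for structural and round-trip tests."""
    return simulate_batch(rei_profile(), 300, seed=7)


@pytest.fixture(scope="session")
def aei_batch():
    return simulate_batch(aei_profile(), 300, seed=11)


@pytest.fixture(scope="session")
def rei_batch_large():
    """Large REI batch for transition-parameter recovery."""
    return simulate_batch(rei_profile(), 5000, seed=1234)
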