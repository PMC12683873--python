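import pytest

from symnorm.fixtures import compound_pulse, left_little_finger, lower_limb_pain


@pytest.fixture
def d1():
    """6年前双下肢疼痛，无肿胀。— time + scope + shared primary + negation."""
    return lower_limb_pain()


@pytest.fixture
def d2():
    """脉弦细弱。— compound pulse: one position, three states."""
    return compound_pulse()


@pytest.fixture
def d3():
    """左手小指疼痛。— progressive position with a scope qualifier."""
    return left_little_finger()
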