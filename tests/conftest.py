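import warnings

import pytest

from wins7.synthetic import (
    make_hollow_shell,
    make_interaction_fixture,
    make_s7_microsite,
    make_tyrosine_pair,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def tyrosine_pair_25():
    return make_tyrosine_pair(ring_rotation_deg=25.0, seed=11)


@pytest.fixture(scope="session")
def hollow_shell():
    return make_hollow_shell(interior_radius=3.0, seed=11)


@pytest.fixture(scope="session")
def gate_open():
    return make_s7_microsite(80.0, seed=0)


@pytest.fixture(scope="session")
def gate_closed():
    return make_s7_microsite(0.0, seed=0)


@pytest.fixture(scope="session")
def hbond_fixture():
    return make_interaction_fixture("hbond_pair", distance=2.8)
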