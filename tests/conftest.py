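"""Shared fixtures: the packaged synthetic-data presets."""

import pytest

from mitotherm import synth


@pytest.fixture(scope="session")
def exp2_preset():
    return synth.load_preset("exp2_suit")


@pytest.fixture(scope="session")
def fig8_preset():
    return synth.load_preset("fig8_ros")


@pytest.fixture(scope="session")
def fig3_preset():
    return synth.load_preset("fig3")


@pytest.fixture(scope="session")
def fig9_preset():
    return synth.load_preset("fig9_kinetics")


@pytest.fixture(scope="session")
def fig10_preset():
    return synth.load_preset("fig10_atp")
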