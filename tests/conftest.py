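import pytest

from aerograph import fixture_moxifloxacin, fixture_toy


@pytest.fixture
def mox():
    return fixture_moxifloxacin("completed_only")


@pytest.fixture
def mox_fig4():
    return fixture_moxifloxacin("figure4")


@pytest.fixture
def toy_fig1():
    return fixture_toy("figure1")


@pytest.fixture
def toy_fig2():
    return fixture_toy("figure2")


@pytest.fixture
def toy_fig3():
    return fixture_toy("figure3")
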