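import numpy as np
import pytest

from lohscape.datasets import midarm_panel, variable_panel, yeast_layout


@pytest.fixture(scope="session")
def layout():
    return yeast_layout()


@pytest.fixture(scope="session")
def panel32(layout):
    return midarm_panel(layout)


@pytest.fixture(scope="session")
def panel23(layout):
    return variable_panel(layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220425)
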