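import numpy as np
import pytest

import mtrsim as m


@pytest.fixture(scope="session")
def phantom128():
    return m.make_phantom(128)


@pytest.fixture(scope="session")
def grid128():
    return m.make_angle_grid(0.0, 360.0, 128)


@pytest.fixture(scope="session")
def sino128(phantom128, grid128):
    return m.forward_project(phantom128, grid128.angles())


@pytest.fixture(scope="session")
def micro():
    return m.load_setup_preset("micro")
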