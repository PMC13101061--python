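import logging

import pytest

import diffuscope as d

# Session-scoped simulation objects shared across test modules: a default
# diffuser screen, a coarse calibration stack (the bench sweep range at a
# 3 mm spacing), and a fundus phantom, all at a 192-px working grid.


@pytest.fixture(scope="session")
def screen192():
    return d.make_phase_screen(seed=0, n=192)


@pytest.fixture(scope="session")
def stack192(screen192):
    return d.build_psf_stack(screen192, (-12.0, 6.0), 3.0)


@pytest.fixture(scope="session")
def phantom192():
    return d.make_fundus_phantom(seed=1, n=192)


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    caplog.set_level(logging.WARNING, logger="diffuscope")
    yield
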