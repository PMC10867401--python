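import numpy as np
import pytest

import plantarkit as pk


@pytest.fixture(scope="session")
def layout():
    return pk.default_layout()


@pytest.fixture(scope="session")
def walk_series():
    """150 cycles of default walking (the standard single-posture record)."""
    return pk.generate_posture_series(pk.Posture.WALK, 150, seed=7)


@pytest.fixture(scope="session")
def quiet_stand():
    """5 s of noise-free standing — a flat baseline for alert fixtures."""
    tpl = pk.default_template(pk.Posture.STAND, noise_sd=0.0)
    return pk.generate_posture_series(pk.Posture.STAND, 9, seed=0, template=tpl)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230921)
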