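import numpy as np
import pytest

WATER_DENSITY = 1000.0  # kg/m^3
GRAVITY = 9.81  # m/s^2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sessile_render():
    """Factory: noiseless spherical-cap image for a given contact angle."""
    from cornerflow.synthetic import gen_sessile_image

    def _make(theta_deg, **kw):
        return gen_sessile_image(theta_deg=theta_deg, **kw)

    return _make


@pytest.fixture
def pendant_render():
    """Factory: pendant-drop image for a given surface tension."""
    from cornerflow.synthetic import gen_pendant_image

    def _make(gamma, **kw):
        return gen_pendant_image(gamma=gamma, **kw)

    return _make
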