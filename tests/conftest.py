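import numpy as np
import pytest

from spcovr import PenaltySettings, center_scale


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_blocks(rng):
    """A well-conditioned 30 x 10 predictor block with a 2-outcome block."""
    x = center_scale(rng.standard_normal((30, 10)))
    y = center_scale(rng.standard_normal((30, 2)))
    return x, y


@pytest.fixture
def rank2_blocks(rng):
    """Noise-free data following a two-component model exactly."""
    i_obs, j_vars = 25, 8
    t = np.linalg.qr(rng.standard_normal((i_obs, 2)))[0]
    px = rng.standard_normal((j_vars, 2))
    py = rng.standard_normal((1, 2))
    x_raw = t @ px.T
    y_raw = t @ py.T
    return center_scale(x_raw), center_scale(y_raw)


def make_settings(alpha=0.5, lambda1=0.0, lambda2=0.0, r=2, constraint="unit_length"):
    return PenaltySettings(
        alpha=alpha,
        lambda1=lambda1,
        lambda2=lambda2,
        n_components=r,
        loading_constraint=constraint,
    )
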