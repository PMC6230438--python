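import numpy as np
import pytest

from limbcpg import (
    DEFAULT_PARAMS,
    DEFAULT_SPEED_MAPS,
    HalfCenterParams,
    LimbCPGParams,
)


@pytest.fixture
def params() -> LimbCPGParams:
    """Optimised cat-walking parameter set."""
    return DEFAULT_PARAMS


@pytest.fixture
def maps():
    """Printed speed-map constants."""
    return DEFAULT_SPEED_MAPS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def random_admissible_draw(rng: np.random.Generator) -> tuple[LimbCPGParams, float]:
    """A random parameter set and drive for which both phases terminate.

    Rates are kept comfortably above |r_leak| so both the exact closed
    form and the simulator are admissible.
    """
    r_leak = -float(rng.uniform(1e-4, 5e-2))
    u = float(rng.uniform(0.5, 10.0))
    hcs = []
    for _ in range(2):
        g = float(rng.uniform(0.05, 3.0))
        x0 = float(rng.uniform(-0.5, 3.0))
        # ensure rate well above the saturation bound
        if x0 + g * u < 10 * abs(r_leak) + 0.05:
            x0 = 10 * abs(r_leak) + 0.05 - g * u + float(rng.uniform(0.0, 1.0))
        hcs.append(HalfCenterParams(x0=x0, g=g))
    return LimbCPGParams(hc1=hcs[0], hc2=hcs[1], r_leak=r_leak), u
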