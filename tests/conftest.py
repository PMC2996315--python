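import numpy as np
import pytest

from xbmech import params


@pytest.fixture(scope="session")
def m1():
    return params.one_spring()


@pytest.fixture(scope="session")
def m2():
    return params.two_spring()


@pytest.fixture(scope="session")
def m4():
    return params.four_spring()


@pytest.fixture(scope="session")
def thermo():
    return params.ThermoParams()


@pytest.fixture(scope="session")
def kin():
    return params.KineticParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231107)


def brute_force_converter_energy(model, tip, state, half_width=6.0,
                                 resolution=0.05):
    """Exhaustive grid search over converter placements (oracle).

    Evaluates the four-spring elastic energy on a dense converter grid
    centred on the rest converter point and returns the minimum.
    """
    from xbmech import geometry

    rests = np.array([s.rest(state) for s in model.springs])
    ks = np.array([s.stiffness for s in model.springs])
    c0 = geometry.rest_converter(model, state)
    g = np.arange(-half_width, half_width + resolution / 2, resolution)
    xc = c0[0] + g[:, None]
    yc = c0[1] + g[None, :]
    xt, yt = tip.axial, tip.radial
    l2 = np.hypot(xc, yc)
    th1 = np.arctan2(yc, xc)
    dx, dy = xt - xc, yt - yc
    l4 = np.hypot(dx, dy)
    th3 = np.arctan2(dy, -dx)
    u = (0.5 * ks[0] * (th1 - rests[0]) ** 2
         + 0.5 * ks[1] * (l2 - rests[1]) ** 2
         + 0.5 * ks[2] * (th3 - rests[2]) ** 2
         + 0.5 * ks[3] * (l4 - rests[3]) ** 2)
    return float(u.min())
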