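import numpy as np
import pytest

import vertexpulse as vp

# Session-scoped tissues are shared read-only; tests must work on .copy().


@pytest.fixture(scope="session")
def hex64():
    return vp.make_hexagonal_tissue(64)


@pytest.fixture(scope="session")
def hex260():
    return vp.make_hexagonal_tissue(260, vp.PeriodicBox(14.0, 18.6))


@pytest.fixture(scope="session")
def disordered100():
    return vp.make_disordered_tissue(100, vp.PeriodicBox(10.0, 10.0), seed=3)


@pytest.fixture(scope="session")
def disordered208():
    return vp.make_disordered_tissue(208, vp.PeriodicBox(14.0, 15.0), seed=1)


@pytest.fixture()
def default_mech():
    return vp.MechParams()


def make_two_vertex_tissue(l=1.0, l0=1.0, box=10.0):
    """Minimal one-junction tissue (no cells) for automaton unit tests."""
    t = vp.Tissue(vp.PeriodicBox(box, box),
                  np.array([[1.0, 1.0], [1.0 + l, 1.0]]),
                  np.array([[0, 1]]), cells=[])
    t.rest_length[:] = l0
    return t
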