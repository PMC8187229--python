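import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse body mesh (level-1 icosphere, 42+1 particles) at R=3."""
    from ciliaswim.swimmer import build_body

    return build_body(3.0, 42)


@pytest.fixture(scope="session")
def anchored_cilium_assembly():
    """One short cilium anchored on a coarse R=3 body."""
    from ciliaswim.swimmer import (anchor_cilium, assemble, build_body,
                                   build_cilium)

    mesh = build_body(3.0, 42)
    cil = build_cilium(3.0, 1.375 * 3.0, 8, (0.0, 0.0))
    anchor_cilium(cil, mesh)
    return assemble(mesh, [cil])
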