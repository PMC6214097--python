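import numpy as np
import pytest

from cuckoodock import (
    DockingBox,
    FixtureSpec,
    make_toy_complex,
    make_toy_ligand,
)


@pytest.fixture
def box():
    """Standard cubic docking box, 22.5 A edges."""
    return DockingBox(np.zeros(3), np.full(3, 22.5))


@pytest.fixture
def chain_topology():
    """6-atom chain ligand with 2 rotatable bonds."""
    return make_toy_ligand(6, 2, seed=1)


@pytest.fixture(scope="session")
def toy_complex():
    """Synthetic complex with a known global-minimum pose (tau=2)."""
    return make_toy_complex(FixtureSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
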