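import numpy as np
import pytest

from ponqsar.dataset import load_pon1
from ponqsar.geometry import embed_conformer, geometry_from_arrays

ELEMENTS = ["C", "H", "O", "N", "S"]


@pytest.fixture(scope="session")
def pon1():
    return load_pon1()


@pytest.fixture(scope="session")
def gbl_geom():
    """γ-butyrolactone conformer (C4H6O2, 12 atoms with hydrogens)."""
    return embed_conformer("O=C1CCCO1", seed=7, label="gbl")


@pytest.fixture(scope="session")
def undecalactone_geom():
    """Undecano-γ-lactone conformer: long chain, graph diameter >= 8."""
    return embed_conformer("CCCCCCCC1CCC(=O)O1", seed=7, label="ugl")


def make_random_geometry(rng, n_atoms=8, spread=3.0):
    """A connected chain 'molecule' with well-separated random atoms."""
    while True:
        coords = rng.uniform(-spread, spread, size=(n_atoms, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.6:
            break
    elements = [ELEMENTS[i] for i in rng.integers(0, len(ELEMENTS), n_atoms)]
    bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    return geometry_from_arrays(coords, elements, bonds, label="random")


@pytest.fixture
def random_geometry():
    return make_random_geometry(np.random.default_rng(11))


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix via QR."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
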