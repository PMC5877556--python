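import numpy as np
import pytest

from fepb import BornFixtureSpec, Molecule, Region, TetMesh, make_born_mesh


@pytest.fixture
def unit_right_tet() -> TetMesh:
    """The reference right tetrahedron (volume 1/6), SOLUTE, all faces marked."""
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    tets = np.array([[0, 1, 2, 3]])
    faces = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
    markers = np.full(4, 8)  # OUTER
    return TetMesh(verts, tets, np.array([int(Region.SOLUTE)]), faces, markers)


@pytest.fixture(scope="session")
def coarse_born_mesh() -> TetMesh:
    """Small concentric-sphere mesh shared across read-only tests."""
    return make_born_mesh(BornFixtureSpec(subdiv=1, n_shells_solute=2, n_shells_solvent=8))


@pytest.fixture
def born_ion() -> Molecule:
    return Molecule(np.zeros((1, 3)), [1.0], [1.0])
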