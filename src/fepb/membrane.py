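"""Implicit membrane slab insertion, pore recognition, tilt rotations.

The membrane is a dielectric slab between heights z1 and z2 spanning the
whole box laterally.  Inserting it naively also fills the aqueous channel
of a membrane channel protein; :func:`detect_pore` recognises the pore
elements — including tilted channels — so they can be given back the
solvent dielectric and ionic accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh import Boundary, Region, TetMesh
from .molecule import Molecule

__all__ = [
    "MembraneSpec",
    "PoreDetectionError",
    "label_membrane",
    "detect_pore",
    "relabel_pore",
    "fill_pore_partial",
    "rotate_molecule",
]


@dataclass(frozen=True)
class MembraneSpec:
    """Slab extent [z1, z2] (Angstrom) and its relative dielectric."""

    z1: float
    z2: float
    eps_mem: float = 2.0

    def __post_init__(self):
        if not self.z1 < self.z2:
            raise ValueError("membrane requires z1 < z2")

    @property
    def thickness(self) -> float:
        return self.z2 - self.z1


class PoreDetectionError(RuntimeError):
    pass


def _copy_with_region(mesh: TetMesh, region: np.ndarray) -> TetMesh:
    return TetMesh(mesh.vertices, mesh.tets, region, mesh.boundary_faces,
                   mesh.boundary_markers, box=mesh.box)


def label_membrane(mesh: TetMesh, spec: MembraneSpec) -> TetMesh:
    """Relabel SOLVENT tets with slab-interior centroids as MEMBRANE.

    SOLUTE elements are never touched.  Membership is by element centroid,
    matching the pore-detection criterion so the two operations are exact
    inverses on pore elements.
    """
    if mesh.box is not None:
        lz = mesh.box[2]
        if spec.z1 < -lz / 2 or spec.z2 > lz / 2:
            raise ValueError("membrane slab extends outside the box")
    z = mesh.centroids()[:, 2]
    region = mesh.region.copy()
    sel = (mesh.region == Region.SOLVENT) & (z >= spec.z1) & (z <= spec.z2)
    region[sel] = Region.MEMBRANE
    return _copy_with_region(mesh, region)


def _face_adjacency(mesh: TetMesh):
    """(n_shared_faces, 2) pairs of tets sharing a face."""
    faces = np.sort(mesh.tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3), axis=1)
    tet_of_face = np.repeat(np.arange(mesh.n_tets), 4)
    order = np.lexsort(faces.T)
    f = faces[order]
    t = tet_of_face[order]
    same = (f[1:] == f[:-1]).all(axis=1)
    return np.column_stack([t[:-1][same], t[1:][same]])


def detect_pore(mesh: TetMesh, spec: MembraneSpec, seed="auto") -> np.ndarray:
    """Identify the channel/pore elements inside the slab.

    Starting from a seed element strictly inside the pore, a direction-free
    flood fill over face-adjacent non-SOLUTE elements with centroid in
    [z1, z2] collects the candidate component; face adjacency (rather than
    vertex adjacency) prevents leakage through single shared vertices at
    the pore wall.  Being direction-free, the walk handles channels tilted
    against the membrane normal.

    The component is accepted as a pore only if it reaches solvent both
    above z2 and below z1 (otherwise it is a dead-end cavity) and does not
    touch the lateral box boundary (otherwise the seed sits in the bulk
    membrane, which always extends to the box sides, not in a
    protein-enclosed channel).

    Returns the tet indices; callers relabel them SOLVENT (see
    :func:`relabel_pore`).  ``seed="auto"`` starts from the element nearest
    the solute bounding-box centre.
    """
    cent = mesh.centroids()
    z = cent[:, 2]
    in_slab = (z >= spec.z1) & (z <= spec.z2)
    non_solute = mesh.region != Region.SOLUTE

    if isinstance(seed, str) and seed == "auto":
        solute_pts = mesh.vertices[np.unique(mesh.tets[mesh.region == Region.SOLUTE])]
        if len(solute_pts) == 0:
            raise PoreDetectionError("auto seeding requires a SOLUTE region")
        target = 0.5 * (solute_pts.min(axis=0) + solute_pts.max(axis=0))
        cand = np.nonzero(non_solute & in_slab)[0]
        if len(cand) == 0:
            raise PoreDetectionError("no non-solute element inside the slab")
        seed_tet = int(cand[np.argmin(np.linalg.norm(cent[cand] - target, axis=1))])
    else:
        seed = np.asarray(seed, dtype=np.float64)
        from .charges import locate_points

        seed_tet = int(locate_points(mesh, seed[None, :])[0][0])
        if mesh.region[seed_tet] == Region.SOLUTE:
            raise PoreDetectionError("seed point lies inside the SOLUTE region")
        if not in_slab[seed_tet]:
            raise PoreDetectionError("seed element is outside the membrane slab")

    adj = _face_adjacency(mesh)
    allowed = non_solute & in_slab
    above = non_solute & (z > spec.z2)
    below = non_solute & (z < spec.z1)

    # neighbour lists restricted to edges with at least one allowed end
    nbr = {"a": adj[:, 0], "b": adj[:, 1]}
    visited = np.zeros(mesh.n_tets, dtype=bool)
    visited[seed_tet] = True
    frontier = np.array([seed_tet])
    touches_above = touches_below = False
    while len(frontier):
        on_frontier = np.zeros(mesh.n_tets, dtype=bool)
        on_frontier[frontier] = True
        sel = on_frontier[adj[:, 0]] | on_frontier[adj[:, 1]]
        cand = np.concatenate([adj[sel, 0], adj[sel, 1]])
        cand = np.unique(cand)
        touches_above = touches_above or bool(above[cand].any())
        touches_below = touches_below or bool(below[cand].any())
        new = cand[allowed[cand] & ~visited[cand]]
        visited[new] = True
        frontier = new
    component = np.nonzero(visited)[0]

    lateral = mesh.boundary_faces[np.isin(mesh.boundary_markers,
                                          [int(m) for m in (Boundary.X_MIN, Boundary.X_MAX,
                                                            Boundary.Y_MIN, Boundary.Y_MAX)])]
    if len(lateral):
        lateral_verts = np.unique(lateral)
        touches_side = np.isin(mesh.tets[component], lateral_verts).any()
        if touches_side:
            raise PoreDetectionError(
                "component reaches the lateral box boundary: seed lies in the bulk "
                "membrane, not in a protein-enclosed channel"
            )
    if not (touches_above and touches_below):
        raise PoreDetectionError(
            "dead-end cavity: component does not reach solvent on both sides of the slab"
        )
    return component


def relabel_pore(mesh: TetMesh, pore: np.ndarray) -> TetMesh:
    """Give the detected pore elements back the SOLVENT label."""
    region = mesh.region.copy()
    region[pore] = Region.SOLVENT
    return _copy_with_region(mesh, region)


def fill_pore_partial(mesh: TetMesh, pore: np.ndarray, hmp: float, spec: MembraneSpec) -> TetMesh:
    """Fill the central band of the pore with membrane (the HMP experiment).

    Pore elements whose centroid lies within the band of height ``hmp``
    centred at the slab midplane are labelled MEMBRANE, emulating a failure
    to recognise (part of) the channel.  ``hmp = 0`` is the identity.
    """
    if hmp < 0 or hmp > spec.thickness + 1e-12:
        raise ValueError("hmp must lie in [0, z2 - z1]")
    if hmp == 0:
        return _copy_with_region(mesh, mesh.region.copy())
    zc = 0.5 * (spec.z1 + spec.z2)
    z = mesh.centroids()[:, 2]
    region = mesh.region.copy()
    band = np.abs(z[pore] - zc) <= hmp / 2.0
    region[np.asarray(pore)[band]] = Region.MEMBRANE
    return _copy_with_region(mesh, region)


def rotate_molecule(mol: Molecule, angle_deg: float, axis=(0.0, 1.0, 0.0)) -> Molecule:
    """Rigid rotation about an in-membrane-plane axis through the centroid.

    Used by the tilt-angle scan; charges and radii are untouched.
    """
    axis = np.asarray(axis, dtype=np.float64)
    if abs(axis[2]) > 1e-12:
        raise ValueError("tilt axis must lie in the x-y (membrane) plane")
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    c = mol.centroid()
    return Molecule(rot.apply(mol.positions - c) + c, mol.charges.copy(), mol.radii.copy())
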