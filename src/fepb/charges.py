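"""Treatments of the singular fixed charges on the right-hand side.

Four strategies for representing delta-function point charges in the P1
weak form:

* direct integral — evaluate the test functions at the charge positions
  (no spreading): ``b_j = sum_i q_i * Phi_j(r_i)``;
* vertex-on-charge — nodal density ``c_j = 4 q_j / |T_j|`` when every
  charge sits exactly on a mesh vertex;
* average assignment — equal nodal density coefficients on all vertices
  within a truncation radius, rescaled to conserve the charge;
* weighted assignment — barycentric-coordinate weights on the containing
  tet's vertices, rescaled to conserve the charge.

All assignment densities satisfy exact integral invariance: the P1
integral of the assigned density equals the molecular charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import Region, TetMesh
from .molecule import Molecule

__all__ = [
    "PointChargeLoad",
    "NodalChargeDensity",
    "barycentric_coords",
    "locate_points",
    "interpolate",
    "vertex_patch_volumes",
    "direct_load",
    "assign_vertex_on_charge",
    "assign_average",
    "assign_weighted",
]

_BARY_TOL = -1e-10  # relative slack on the smallest barycentric coordinate


def barycentric_coords(tet_vertices: np.ndarray, point) -> np.ndarray:
    """Barycentric coordinates (lambda_1..lambda_4) of a point in one tet.

    Computed as signed sub-tet volume ratios; the coordinates sum to 1 and
    are non-negative (to tolerance) for interior points.
    """
    v = np.asarray(tet_vertices, dtype=np.float64)
    p = np.asarray(point, dtype=np.float64)
    e = (v[1:] - v[0]).T  # 3x3
    det = np.linalg.det(e)
    if abs(det) < 1e-14 * max(1.0, np.abs(e).max() ** 3):
        raise ValueError("degenerate tetrahedron")
    lam123 = np.linalg.solve(e, p - v[0])
    return np.concatenate([[1.0 - lam123.sum()], lam123])


def _all_barycentric(mesh: TetMesh, tet_ids: np.ndarray, points: np.ndarray) -> np.ndarray:
    """(k, 4) barycentric coords of points[i] in tets[tet_ids[i]], vectorized."""
    v = mesh.vertices[mesh.tets[tet_ids]]  # (k,4,3)
    e = np.transpose(v[:, 1:] - v[:, :1], (0, 2, 1))  # (k,3,3)
    lam123 = np.linalg.solve(e, (points - v[:, 0])[..., None])[..., 0]
    lam0 = 1.0 - lam123.sum(axis=1)
    return np.column_stack([lam0, lam123])


def locate_points(mesh: TetMesh, points, _k0: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Find the containing tet for each point.

    Returns ``(tet_ids, lambdas)``.  Candidate tets come from a k-d tree on
    centroids with an exhaustive fallback; ties on shared faces resolve to
    the lowest tet index.  Raises ValueError when a point is outside the
    mesh.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    npts = len(points)
    tree = cKDTree(mesh.centroids())
    tet_ids = np.full(npts, -1, dtype=np.int64)
    lams = np.zeros((npts, 4))
    pending = np.arange(npts)
    k = min(_k0, mesh.n_tets)
    while len(pending) and k <= mesh.n_tets:
        _, cand = tree.query(points[pending], k=k)
        cand = np.atleast_2d(cand)
        cand.sort(axis=1)  # lowest tet index wins ties
        for row, pi in enumerate(pending):
            lam = _all_barycentric(mesh, cand[row], np.repeat(points[pi : pi + 1], cand.shape[1], axis=0))
            ok = np.nonzero(lam.min(axis=1) >= _BARY_TOL)[0]
            if len(ok):
                tet_ids[pi] = cand[row, ok[0]]
                lams[pi] = lam[ok[0]]
        pending = np.nonzero(tet_ids < 0)[0]
        if k == mesh.n_tets:
            break
        k = min(4 * k, mesh.n_tets)
    if len(pending):
        raise ValueError(f"point(s) outside the mesh: indices {pending.tolist()[:5]}")
    return tet_ids, lams


def interpolate(mesh: TetMesh, nodal: np.ndarray, points, located=None) -> np.ndarray:
    """P1 interpolation of a nodal field at arbitrary points."""
    if located is None:
        located = locate_points(mesh, points)
    tet_ids, lams = located
    return (np.asarray(nodal)[mesh.tets[tet_ids]] * lams).sum(axis=1)


def vertex_patch_volumes(mesh: TetMesh) -> np.ndarray:
    """|T_j|: total volume of the tets containing each vertex."""
    vols = mesh.volumes()
    out = np.zeros(mesh.n_vertices)
    for c in range(4):
        np.add.at(out, mesh.tets[:, c], vols)
    return out


# ---------------------------------------------------------------------------
# Load representations
# ---------------------------------------------------------------------------

@dataclass
class PointChargeLoad:
    """Per-vertex load ``b_j = sum_i q_i Phi_j(r_i)`` (elementary charges).

    The partition of unity of the P1 basis makes ``sum_j b_j`` equal the
    molecular net charge exactly.
    """

    values: np.ndarray

    def load_vector(self, mesh: TetMesh) -> np.ndarray:
        return self.values

    def total_charge(self, mesh: TetMesh) -> float:
        return float(self.values.sum())


@dataclass
class NodalChargeDensity:
    """P1 density ``rho* = sum_j c_j Phi_j`` (e / A^3) spreading the charges.

    ``integral`` is the exact P1 integral ``sum_j c_j |T_j| / 4``; the load
    vector lumps the nodal charge ``c_j |T_j| / 4`` as a delta at node j, so
    a density whose charge sits on a vertex produces the identical load as
    the direct-integral treatment.
    """

    coefficients: np.ndarray

    def node_charges(self, mesh: TetMesh) -> np.ndarray:
        return self.coefficients * vertex_patch_volumes(mesh) / 4.0

    def load_vector(self, mesh: TetMesh) -> np.ndarray:
        return self.node_charges(mesh)

    def total_charge(self, mesh: TetMesh) -> float:
        return float(self.node_charges(mesh).sum())


def _located_in_solute(mol: Molecule, mesh: TetMesh):
    tet_ids, lams = locate_points(mesh, mol.positions)
    bad = np.nonzero(mesh.region[tet_ids] != Region.SOLUTE)[0]
    if len(bad):
        raise ValueError(f"atom(s) outside the solute region: indices {bad.tolist()[:5]}")
    return tet_ids, lams


def direct_load(mol: Molecule, mesh: TetMesh, located=None) -> PointChargeLoad:
    """Direct integral of the singular source: no charge spreading."""
    if located is None:
        located = _located_in_solute(mol, mesh)
    tet_ids, lams = located
    b = np.zeros(mesh.n_vertices)
    np.add.at(b, mesh.tets[tet_ids], mol.charges[:, None] * lams)
    return PointChargeLoad(b)


def assign_vertex_on_charge(mol: Molecule, mesh: TetMesh, tol: float = 1e-9) -> NodalChargeDensity:
    """Nodal density for charges constrained to mesh vertices.

    Integral invariance forces ``c_j = 4 q_j / |T_j|`` at the charge's
    vertex.  Raises if any atom is farther than ``tol`` from a vertex.
    """
    tree = cKDTree(mesh.vertices)
    dist, vid = tree.query(mol.positions)
    bad = np.nonzero(dist > tol)[0]
    if len(bad):
        raise ValueError(f"atom(s) not on a mesh vertex: indices {bad.tolist()[:5]}")
    patch = vertex_patch_volumes(mesh)
    c = np.zeros(mesh.n_vertices)
    np.add.at(c, vid, 4.0 * mol.charges / patch[vid])
    return NodalChargeDensity(c)


def assign_average(mol: Molecule, mesh: TetMesh, r_cut: float = 1.0) -> NodalChargeDensity:
    """Equal spreading onto all vertices within a truncation sphere.

    Every enclosed vertex gets the same provisional density coefficient;
    each charge's set is rescaled so its P1 integral equals the charge
    (per-charge rescaling, contributions superposed).
    """
    tree = cKDTree(mesh.vertices)
    patch = vertex_patch_volumes(mesh)
    c = np.zeros(mesh.n_vertices)
    for i, (p, q) in enumerate(zip(mol.positions, mol.charges)):
        vids = tree.query_ball_point(p, r_cut)
        if not vids:
            raise ValueError(
                f"no mesh vertex within r_cut={r_cut} A of atom {i}; increase r_cut"
            )
        vids = np.asarray(vids)
        # equal coefficients a: integral = a * sum(|T_k|)/4 = q
        c[vids] += q * 4.0 / patch[vids].sum()
    return NodalChargeDensity(c)


def assign_weighted(mol: Molecule, mesh: TetMesh, located=None) -> NodalChargeDensity:
    """Barycentric-weighted spreading onto the containing tet's vertices.

    Vertex k receives the provisional coefficient ``lambda_k q_i``; the four
    are scaled by ``4 / sum_k |T_k| lambda_k`` so the P1 integral equals
    ``q_i``.  A charge sitting on a vertex reduces exactly to the
    vertex-on-charge density.
    """
    if located is None:
        located = _located_in_solute(mol, mesh)
    tet_ids, lams = located
    patch = vertex_patch_volumes(mesh)
    verts = mesh.tets[tet_ids]  # (n,4)
    scale = 4.0 / (patch[verts] * lams).sum(axis=1)
    c = np.zeros(mesh.n_vertices)
    np.add.at(c, verts, (mol.charges * scale)[:, None] * lams)
    return NodalChargeDensity(c)
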