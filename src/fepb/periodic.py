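"""Lateral (x/y) periodic boundary conditions via DOF identification.

Opposite box faces must be translation-consistent: every vertex on X_MIN
has exactly one partner on X_MAX at offset (Lx, 0, 0), and likewise in y.
Matching vertices are "stitched" into a single unknown: the assembled
system is folded by summing slave rows/columns onto their masters, which
is algebraically identical to meshing the faces as shared interior faces.
The z direction is never periodic (Dirichlet on TOP/BOTTOM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Boundary, TetMesh

__all__ = ["PeriodicMap", "PeriodicityError", "build_periodic_map"]


class PeriodicityError(ValueError):
    """Opposite box faces are not translation-consistent."""


@dataclass
class PeriodicMap:
    """Slave->master vertex pairs and the reduced unknown numbering.

    ``reduced_dof_of_vertex[v]`` maps every mesh vertex to its reduced
    unknown; slaves share their master's index.  Corner/edge vertices chain
    to a single master (no vertex is both master and slave after chain
    resolution).
    """

    pairs: np.ndarray  # (k, 2) slave, master vertex indices
    reduced_dof_of_vertex: np.ndarray  # (n,) int
    n_reduced: int


def _match_faces(verts: np.ndarray, slave_ids: np.ndarray, master_ids: np.ndarray,
                 axes: tuple[int, int], tol: float, label: str) -> np.ndarray:
    """Pair each slave with its master by the in-plane coordinates."""
    if len(slave_ids) != len(master_ids):
        raise PeriodicityError(
            f"{label}: {len(slave_ids)} vertices on the max face vs {len(master_ids)} on the min face"
        )
    sc = verts[np.ix_(slave_ids, axes)]
    mc = verts[np.ix_(master_ids, axes)]
    s_order = np.lexsort((sc[:, 1], sc[:, 0]))
    m_order = np.lexsort((mc[:, 1], mc[:, 0]))
    ds = np.abs(sc[s_order] - mc[m_order]).max(axis=1) if len(s_order) else np.zeros(0)
    bad = np.nonzero(ds > tol)[0]
    if len(bad):
        i = bad[0]
        raise PeriodicityError(
            f"{label}: faces not translation-consistent; unmatched vertex near "
            f"{verts[slave_ids[s_order[i]]].tolist()} vs {verts[master_ids[m_order[i]]].tolist()}"
        )
    return np.column_stack([slave_ids[s_order], master_ids[m_order]])


def build_periodic_map(mesh: TetMesh, tol: float | None = None) -> PeriodicMap:
    """Build the x/y periodic identification for a box mesh.

    Matching is by lexicographically sorted in-plane coordinates
    (O(n log n)).  ``tol`` defaults to ``1e-6 * max(Lx, Ly)``.  Chains
    (x-pair, y-pair, shared vertical box edges) are resolved by union-find
    so every equivalence class has one master unknown.
    """
    if mesh.box is None:
        raise ValueError("periodic map requires a box mesh")
    lx, ly, _ = mesh.box
    if tol is None:
        tol = 1e-6 * max(lx, ly)

    pairs = []
    for mk_max, mk_min, axes, label in (
        (Boundary.X_MAX, Boundary.X_MIN, (1, 2), "x faces"),
        (Boundary.Y_MAX, Boundary.Y_MIN, (0, 2), "y faces"),
    ):
        slaves = mesh.boundary_vertices(mk_max)
        masters = mesh.boundary_vertices(mk_min)
        pairs.append(_match_faces(mesh.vertices, slaves, masters, axes, tol, label))
    all_pairs = np.vstack(pairs)

    # union-find chain resolution (lowest vertex index becomes the root)
    parent = np.arange(mesh.n_vertices)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for s, m in all_pairs:
        rs, rm = find(s), find(m)
        if rs != rm:
            hi, lo = max(rs, rm), min(rs, rm)
            parent[hi] = lo

    roots = np.array([find(i) for i in range(mesh.n_vertices)])
    masters, reduced = np.unique(roots, return_inverse=True)
    slave_sel = roots != np.arange(mesh.n_vertices)
    resolved_pairs = np.column_stack([np.nonzero(slave_sel)[0], roots[slave_sel]])
    return PeriodicMap(pairs=resolved_pairs, reduced_dof_of_vertex=reduced, n_reduced=len(masters))
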