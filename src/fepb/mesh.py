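"""Tetrahedral mesh data model, TetGen-style I/O, uniform refinement.

The mesh is the single geometric substrate of the solver: linear (P1)
tetrahedra with a region label per element (solute / solvent / membrane
slab) and marked boundary triangles.  Coordinates are in Angstrom and the
membrane normal is always the z axis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Region",
    "Boundary",
    "TetMesh",
    "MeshFormatError",
    "read_tetgen",
    "write_tetgen",
    "write_vtk",
    "refine_uniform",
    "equivalent_edge_length",
]


class Region(enum.IntEnum):
    """Element region labels partitioning the domain."""

    SOLUTE = 1
    SOLVENT = 2
    MEMBRANE = 3


class Boundary(enum.IntEnum):
    """Boundary-face markers.

    TOP/BOTTOM are the z faces of the box (always Dirichlet), X_*/Y_* the
    lateral faces (Dirichlet or periodic), OUTER the outer sphere of
    unbounded (Born-type) meshes, INTERFACE the solute surface.
    """

    TOP = 1
    BOTTOM = 2
    X_MIN = 3
    X_MAX = 4
    Y_MIN = 5
    Y_MAX = 6
    INTERFACE = 7
    OUTER = 8


#: markers that always carry Dirichlet data
DIRICHLET_MARKERS = (Boundary.TOP, Boundary.BOTTOM, Boundary.OUTER)
#: lateral markers, periodic or Dirichlet depending on bc mode
LATERAL_MARKERS = (Boundary.X_MIN, Boundary.X_MAX, Boundary.Y_MIN, Boundary.Y_MAX)

# default TetGen region-attribute -> label map
DEFAULT_REGION_MAP = {1: Region.SOLUTE, 2: Region.SOLVENT, 3: Region.MEMBRANE}


class MeshFormatError(ValueError):
    """Raised for malformed TetGen-style input files."""


@dataclass
class TetMesh:
    """Conforming tetrahedral mesh with region and boundary markers.

    Attributes
    ----------
    vertices : (n, 3) float array, Angstrom.
    tets : (m, 4) int array; positive signed volume under the stored order.
    region : (m,) int array of :class:`Region` values.
    boundary_faces : (k, 3) int array of vertex triples.
    boundary_markers : (k,) int array of :class:`Boundary` values.
    box : ``(Lx, Ly, Lz)`` extents of a box mesh centred at the origin, or
        ``None`` for unbounded (concentric-sphere) meshes.
    """

    vertices: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    boundary_faces: np.ndarray
    boundary_markers: np.ndarray
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.region = np.ascontiguousarray(self.region, dtype=np.int64)
        self.boundary_faces = np.ascontiguousarray(self.boundary_faces, dtype=np.int64).reshape(-1, 3)
        self.boundary_markers = np.ascontiguousarray(self.boundary_markers, dtype=np.int64)

    # -- basic geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_vertices(self) -> np.ndarray:
        """(m, 4, 3) coordinates of the tets' corners."""
        return self.vertices[self.tets]

    def signed_volumes(self) -> np.ndarray:
        v = self.tet_vertices()
        e = v[:, 1:] - v[:, :1]
        return np.linalg.det(e) / 6.0

    def volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def centroids(self) -> np.ndarray:
        return self.tet_vertices().mean(axis=1)

    def orient_positive(self) -> None:
        """Swap vertex order in place so every signed volume is positive."""
        neg = self.signed_volumes() < 0
        self.tets[neg, 2], self.tets[neg, 3] = (
            self.tets[neg, 3].copy(),
            self.tets[neg, 2].copy(),
        )

    def region_volume(self, label: int) -> float:
        return float(self.volumes()[self.region == label].sum())

    def boundary_vertices(self, markers) -> np.ndarray:
        """Sorted unique vertex indices on faces with any of the markers."""
        markers = [int(m) for m in np.atleast_1d(markers)]
        sel = np.isin(self.boundary_markers, markers)
        return np.unique(self.boundary_faces[sel])

    # -- audits ----------------------------------------------------------

    def face_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """All element faces (sorted triples) and their multiplicities."""
        f = _tet_faces(self.tets)
        f = np.sort(f, axis=1)
        return np.unique(f, axis=0, return_counts=True)

    def validate(self, tol: float = 1e-12) -> None:
        """Run the structural invariants; raise AssertionError on failure."""
        vol = self.signed_volumes()
        assert (vol > 0).all(), "non-positive tet volume"
        faces, counts = self.face_counts()
        assert counts.max() <= 2, "face shared by more than two tets"
        nb = int((counts == 1).sum())
        assert nb == len(self.boundary_faces), (
            f"{nb} topological boundary faces but {len(self.boundary_faces)} marked"
        )
        marked = {tuple(f) for f in np.sort(self.boundary_faces, axis=1)}
        topo = {tuple(f) for f in faces[counts == 1]}
        assert marked == topo, "marked boundary faces do not match mesh topology"
        assert np.isin(self.region, list(Region)).all(), "unknown region label"
        if self.box is not None:
            lx, ly, lz = self.box
            t = tol_box = 1e-6 * max(lx, ly, lz)
            for marker, axis, val in (
                (Boundary.X_MIN, 0, -lx / 2), (Boundary.X_MAX, 0, lx / 2),
                (Boundary.Y_MIN, 1, -ly / 2), (Boundary.Y_MAX, 1, ly / 2),
                (Boundary.BOTTOM, 2, -lz / 2), (Boundary.TOP, 2, lz / 2),
            ):
                vs = self.boundary_vertices(marker)
                if len(vs):
                    off = np.abs(self.vertices[vs, axis] - val).max()
                    assert off <= tol_box, f"{marker.name} face off its plane by {off}"


def _tet_faces(tets: np.ndarray) -> np.ndarray:
    """(4m, 3) faces of the tets, face i opposite local vertex i."""
    idx = [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]
    return tets[:, idx].reshape(-1, 3)


# ---------------------------------------------------------------------------
# TetGen-style ASCII I/O
# ---------------------------------------------------------------------------

def _data_lines(path: Path) -> list[list[str]]:
    out = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        s = raw.split("#", 1)[0].strip()
        if s:
            out.append((ln, s.split()))
    return out


def read_tetgen(node_path, ele_path, face_path, region_map=None, box=None) -> TetMesh:
    """Read a TetGen-style ``.node``/``.ele``/``.face`` triple.

    The first index in the node file decides 0- vs 1-based numbering.  The
    ele file must carry a region-attribute column mapped to labels through
    ``region_map`` (default ``{1: SOLUTE, 2: SOLVENT, 3: MEMBRANE}``); the
    face file must carry boundary markers.
    """
    region_map = dict(DEFAULT_REGION_MAP if region_map is None else region_map)
    node_path, ele_path, face_path = Path(node_path), Path(ele_path), Path(face_path)

    lines = _data_lines(node_path)
    ln, hdr = lines[0]
    n = int(hdr[0])
    if len(lines) - 1 < n:
        raise MeshFormatError(f"{node_path}: header promises {n} nodes, found {len(lines) - 1}")
    ids = np.empty(n, dtype=np.int64)
    verts = np.empty((n, 3))
    for i, (ln, f) in enumerate(lines[1 : n + 1]):
        try:
            ids[i] = int(f[0])
            verts[i] = [float(f[1]), float(f[2]), float(f[3])]
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"{node_path}:{ln}: bad node record") from exc
    base = int(ids.min())
    if base not in (0, 1):
        raise MeshFormatError(f"{node_path}: first index must be 0 or 1, got {base}")
    order = np.argsort(ids)
    verts = verts[order]

    lines = _data_lines(ele_path)
    ln0, hdr = lines[0]
    m = int(hdr[0])
    nattr = int(hdr[2]) if len(hdr) > 2 else 0
    if nattr < 1:
        raise MeshFormatError(f"{ele_path}: no region-attribute column in header")
    tets = np.empty((m, 4), dtype=np.int64)
    region = np.empty(m, dtype=np.int64)
    for i, (ln, f) in enumerate(lines[1 : m + 1]):
        try:
            tets[i] = [int(x) for x in f[1:5]]
            attr = int(float(f[5]))
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"{ele_path}:{ln}: bad element record") from exc
        if attr not in region_map:
            raise MeshFormatError(f"{ele_path}:{ln}: region attribute {attr} not in region map")
        region[i] = int(region_map[attr])
        if (tets[i] - base < 0).any() or (tets[i] - base >= n).any():
            raise MeshFormatError(f"{ele_path}:{ln}: vertex index out of range")
    tets -= base

    lines = _data_lines(face_path)
    ln0, hdr = lines[0]
    k = int(hdr[0])
    nbm = int(hdr[1]) if len(hdr) > 1 else 0
    if nbm < 1:
        raise MeshFormatError(f"{face_path}: no boundary-marker column in header")
    faces = np.empty((k, 3), dtype=np.int64)
    markers = np.empty(k, dtype=np.int64)
    for i, (ln, f) in enumerate(lines[1 : k + 1]):
        try:
            faces[i] = [int(x) for x in f[1:4]]
            markers[i] = int(f[4])
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"{face_path}:{ln}: bad face record") from exc
        if (faces[i] - base < 0).any() or (faces[i] - base >= n).any():
            raise MeshFormatError(f"{face_path}:{ln}: vertex index out of range")
    faces -= base

    mesh = TetMesh(verts, tets, region, faces, markers, box=box)
    mesh.orient_positive()
    return mesh


def write_tetgen(mesh: TetMesh, stem) -> tuple[Path, Path, Path]:
    """Write ``<stem>.node/.ele/.face`` with 1-based indices (TetGen default)."""
    stem = Path(stem)
    node, ele, face = (stem.with_suffix(s) for s in (".node", ".ele", ".face"))
    with open(node, "w") as fh:
        fh.write(f"{mesh.n_vertices} 3 0 0\n")
        for i, (x, y, z) in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    with open(ele, "w") as fh:
        fh.write(f"{mesh.n_tets} 4 1\n")
        for i, (t, r) in enumerate(zip(mesh.tets + 1, mesh.region), start=1):
            fh.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]} {r}\n")
    with open(face, "w") as fh:
        fh.write(f"{len(mesh.boundary_faces)} 1\n")
        for i, (f, mk) in enumerate(zip(mesh.boundary_faces + 1, mesh.boundary_markers), start=1):
            fh.write(f"{i} {f[0]} {f[1]} {f[2]} {mk}\n")
    return node, ele, face


def write_vtk(mesh: TetMesh, path, point_data=None, cell_data=None) -> Path:
    """Write a legacy ASCII VTK unstructured grid for visualization.

    ``point_data``/``cell_data`` are optional ``{name: 1-D array}`` dicts;
    the region label is always written as cell data.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfepb mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        np.savetxt(fh, mesh.vertices, fmt="%.10g")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        cells = np.hstack([np.full((mesh.n_tets, 1), 4, dtype=np.int64), mesh.tets])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(fh, np.full(mesh.n_tets, 10, dtype=np.int64), fmt="%d")
        fh.write(f"CELL_DATA {mesh.n_tets}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.region, fmt="%d")
        for name, arr in (cell_data or {}).items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(arr), fmt="%.10g")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr), fmt="%.10g")
    return path


# ---------------------------------------------------------------------------
# Uniform refinement (octasection)
# ---------------------------------------------------------------------------

_EDGE_LOCAL = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])

# octahedron child tets for the three interior-diagonal choices, in terms of
# midpoint local edge ids (0:m01 1:m02 2:m03 3:m12 4:m13 5:m23)
_OCTA_SPLITS = {
    0: [(0, 5, 1, 2), (0, 5, 2, 4), (0, 5, 4, 3), (0, 5, 3, 1)],  # diag m01-m23
    1: [(1, 4, 0, 2), (1, 4, 2, 5), (1, 4, 5, 3), (1, 4, 3, 0)],  # diag m02-m13
    2: [(2, 3, 0, 1), (2, 3, 1, 5), (2, 3, 5, 4), (2, 3, 4, 0)],  # diag m03-m12
}


def refine_uniform(mesh: TetMesh, snap=None) -> TetMesh:
    """Octasection: split every tet into 8 via edge midpoints.

    The interior octahedron is cut along the shortest of its three
    diagonals (quality preserving).  Children inherit the parent region
    label; boundary faces split into 4 children with the parent marker.

    ``snap``, if given, is called as ``snap(mid, pa, pb)`` with the midpoint
    coordinates and the two parent endpoints of each new vertex and must
    return adjusted coordinates — used for curved-geometry (e.g. radial)
    refinement.  Without it, refinement tiles the parent exactly and
    conserves volume per region.
    """
    nv = mesh.n_vertices
    pairs = np.sort(mesh.tets[:, _EDGE_LOCAL], axis=2).reshape(-1, 2)
    keys = pairs[:, 0] * nv + pairs[:, 1]
    uniq, inverse = np.unique(keys, return_inverse=True)
    ua, ub = uniq // nv, uniq % nv
    pa, pb = mesh.vertices[ua], mesh.vertices[ub]
    mid = 0.5 * (pa + pb)
    if snap is not None:
        mid = np.asarray(snap(mid, pa, pb), dtype=np.float64)
    new_vertices = np.vstack([mesh.vertices, mid])

    # (m, 6) global ids of the edge midpoints of each tet
    emid = (nv + inverse).reshape(-1, 6)
    t = mesh.tets
    corner = np.stack(
        [
            np.stack([t[:, 0], emid[:, 0], emid[:, 1], emid[:, 2]], axis=1),
            np.stack([emid[:, 0], t[:, 1], emid[:, 3], emid[:, 4]], axis=1),
            np.stack([emid[:, 1], emid[:, 3], t[:, 2], emid[:, 5]], axis=1),
            np.stack([emid[:, 2], emid[:, 4], emid[:, 5], t[:, 3]], axis=1),
        ],
        axis=1,
    )  # (m, 4, 4)

    dlen = np.stack(
        [
            np.linalg.norm(new_vertices[emid[:, a]] - new_vertices[emid[:, b]], axis=1)
            for a, b in ((0, 5), (1, 4), (2, 3))
        ],
        axis=1,
    )
    choice = np.argmin(dlen, axis=1)
    octa = np.empty((mesh.n_tets, 4, 4), dtype=np.int64)
    for c, split in _OCTA_SPLITS.items():
        sel = choice == c
        if sel.any():
            octa[sel] = emid[np.ix_(sel, np.array(split).ravel())].reshape(-1, 4, 4)

    children = np.concatenate([corner, octa], axis=1).reshape(-1, 4)
    child_region = np.repeat(mesh.region, 8)

    # boundary faces: 4 children each; look the midpoints up in the edge table
    bf = mesh.boundary_faces
    fpairs = np.sort(bf[:, [[0, 1], [1, 2], [0, 2]]], axis=2).reshape(-1, 2)
    fkeys = fpairs[:, 0] * nv + fpairs[:, 1]
    pos = np.searchsorted(uniq, fkeys)
    fmid = (nv + pos).reshape(-1, 3)  # m01, m12, m02 per face (a,b,c)
    a, b, c = bf[:, 0], bf[:, 1], bf[:, 2]
    child_faces = np.concatenate(
        [
            np.stack([a, fmid[:, 0], fmid[:, 2]], axis=1),
            np.stack([b, fmid[:, 1], fmid[:, 0]], axis=1),
            np.stack([c, fmid[:, 2], fmid[:, 1]], axis=1),
            fmid,
        ]
    )
    child_markers = np.tile(mesh.boundary_markers, 4)

    out = TetMesh(new_vertices, children, child_region, child_faces, child_markers, box=mesh.box)
    out.orient_positive()
    return out


def equivalent_edge_length(mesh: TetMesh, center, radius: float) -> float:
    """Edge length of the regular tet matching the mean element volume.

    Averages the volumes of tets whose centroid lies within ``radius`` of
    ``center`` and returns ``a = (6*sqrt(2)*Vbar)**(1/3)`` — the resolution
    metric used to compare with finite-difference grid spacings.
    """
    center = np.asarray(center, dtype=np.float64)
    d = np.linalg.norm(mesh.centroids() - center, axis=1)
    sel = d <= radius
    if not sel.any():
        raise ValueError("no tet centroid inside the probe sphere")
    vbar = mesh.volumes()[sel].mean()
    return float((6.0 * np.sqrt(2.0) * vbar) ** (1.0 / 3.0))
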