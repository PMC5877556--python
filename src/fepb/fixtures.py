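"""Synthetic meshes and molecules for testing and desk-scale experiments.

Two mesh families, built without any external mesher:

* concentric-sphere Born meshes — layered icosphere shells, radially
  graded from the solute ball out to a far boundary, with the charge on a
  centre vertex (supports the vertex-on-charge treatment);
* periodic-ready box meshes — tensor-product grids split into 6 tets per
  cube (Kuhn/Freudenthal pattern, translation-consistent on opposite
  faces), with an optional cylindrical channel "protein" plug (tiltable)
  or a central spherical solute for charge clusters.

The dielectric boundary of the box meshes follows element centroids and
is therefore staircase-like: adequate for trend and property studies, not
for high-accuracy single-ion benchmarks (that is the Born family's job).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Boundary, Region, TetMesh, refine_uniform
from .molecule import Molecule

__all__ = [
    "BornFixtureSpec",
    "ChannelFixtureSpec",
    "make_born_mesh",
    "radial_snap",
    "born_mesh_levels",
    "make_box_mesh",
    "make_channel_system",
    "make_random_cluster",
    "graded_axis",
]


# ---------------------------------------------------------------------------
# Icosphere machinery
# ---------------------------------------------------------------------------

def _icosahedron():
    p = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, p, 0], [1, p, 0], [-1, -p, 0], [1, -p, 0],
            [0, -1, p], [0, 1, p], [0, -1, -p], [0, 1, -p],
            [p, 0, -1], [p, 0, 1], [-p, 0, -1], [-p, 0, 1],
        ],
        dtype=np.float64,
    )
    v /= np.linalg.norm(v, axis=1)[:, None]
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


def icosphere(subdiv: int):
    """Unit-sphere triangulation: icosahedron with ``subdiv`` 4-splits."""
    v, f = _icosahedron()
    for _ in range(subdiv):
        verts = list(v)
        cache = {}

        def mid(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = 0.5 * (verts[i] + verts[j])
                m /= np.linalg.norm(m)
                cache[key] = len(verts)
                verts.append(m)
            return cache[key]

        nf = []
        for a, b, c in f:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            nf += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v, f = np.array(verts), np.array(nf, dtype=np.int64)
    return v, f


def _split_prism(a, b):
    """Split a prism (bottom triple a, top triple b) into 3 tets.

    The interior diagonals follow the per-quad minimum-global-index rule
    so neighbouring prisms triangulate shared quads identically.
    """
    six = [a[0], a[1], a[2], b[0], b[1], b[2]]
    m = int(np.argmin(six))
    if m >= 3:  # smallest vertex on top: mirror the prism
        a, b = b, a
        m -= 3
    a = (a[m], a[(m + 1) % 3], a[(m + 2) % 3])
    b = (b[m], b[(m + 1) % 3], b[(m + 2) % 3])
    if min(a[1], b[2]) < min(a[2], b[1]):  # third-quad diagonal a1-b2
        return [
            (a[0], a[1], a[2], b[2]),
            (a[0], a[1], b[2], b[1]),
            (a[0], b[1], b[2], b[0]),
        ]
    return [
        (a[0], a[1], a[2], b[1]),
        (a[0], a[2], b[2], b[1]),
        (a[0], b[0], b[1], b[2]),
    ]


@dataclass(frozen=True)
class BornFixtureSpec:
    """Concentric-sphere mesh: solute ball r_in inside a far boundary r_out.

    ``subdiv`` sets the angular resolution (icosphere subdivisions),
    ``n_shells_solute``/``n_shells_solvent`` the radial layer counts, and
    ``grading`` warps the geometric radius schedule (1 = plain geometric).
    With ``vertex_on_center`` the charge position coincides with a mesh
    vertex; otherwise the centre vertex is nudged off the origin.
    """

    r_in: float = 1.0
    r_out: float = 200.0
    subdiv: int = 2
    n_shells_solute: int = 2
    n_shells_solvent: int = 16
    grading: float = 1.0
    vertex_on_center: bool = True

    def __post_init__(self):
        if not 0 < self.r_in < self.r_out:
            raise ValueError("need 0 < r_in < r_out")

    def radii(self) -> np.ndarray:
        inner = self.r_in * np.arange(1, self.n_shells_solute + 1) / self.n_shells_solute
        t = (np.arange(1, self.n_shells_solvent + 1) / self.n_shells_solvent) ** self.grading
        outer = self.r_in * (self.r_out / self.r_in) ** t
        return np.concatenate([inner, outer])


def make_born_mesh(spec: BornFixtureSpec = BornFixtureSpec()) -> TetMesh:
    """Layered icosphere-shell mesh for the single-ion benchmark."""
    sv, sf = icosphere(spec.subdiv)
    nv = len(sv)
    radii = spec.radii()
    center = np.zeros((1, 3))
    if not spec.vertex_on_center:
        center = center + 0.12 * radii[0] * np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    vertices = np.vstack([center] + [sv * r for r in radii])

    tets = []
    for tri in sf:  # innermost ball around the centre vertex
        tets.append((0, 1 + tri[0], 1 + tri[1], 1 + tri[2]))
    for layer in range(len(radii) - 1):
        lo, hi = 1 + layer * nv, 1 + (layer + 1) * nv
        for tri in sf:
            tets += _split_prism(tuple(lo + tri), tuple(hi + tri))
    tets = np.array(tets, dtype=np.int64)

    bnd = (1 + (len(radii) - 1) * nv) + sf
    markers = np.full(len(bnd), int(Boundary.OUTER))
    mesh = TetMesh(vertices, tets, np.zeros(len(tets)), bnd, markers, box=None)
    mesh.orient_positive()
    cent_r = np.linalg.norm(mesh.centroids(), axis=1)
    mesh.region = np.where(cent_r < spec.r_in, int(Region.SOLUTE), int(Region.SOLVENT)).astype(np.int64)
    return mesh


def radial_snap(mid: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Refinement snap projecting new vertices onto their mean radius.

    Keeps refined concentric-sphere meshes body-fitted: midpoints of
    same-shell edges return to the shell sphere, radial edges are
    untouched.
    """
    target = 0.5 * (np.linalg.norm(pa, axis=1) + np.linalg.norm(pb, axis=1))
    nm = np.linalg.norm(mid, axis=1)
    scale = np.where(nm > 1e-30, target / np.maximum(nm, 1e-30), 1.0)
    return mid * scale[:, None]


def born_mesh_levels(spec: BornFixtureSpec, n_levels: int, snap: bool = False) -> list[TetMesh]:
    """Level-0 Born mesh plus ``n_levels`` uniform refinements.

    ``snap=True`` projects new vertices radially (body-fitted refinement);
    the default keeps the polyhedral geometry fixed (plain octasection).
    """
    meshes = [make_born_mesh(spec)]
    for _ in range(n_levels):
        meshes.append(refine_uniform(meshes[-1], snap=radial_snap if snap else None))
    return meshes


# ---------------------------------------------------------------------------
# Tensor-product box meshes (periodic-ready)
# ---------------------------------------------------------------------------

def graded_axis(L: float, fine_halfwidth: float, h_fine: float,
                growth: float = 1.5, h_max: float = 8.0) -> np.ndarray:
    """Symmetric axis coordinates on [-L/2, L/2]: fine core, graded tails."""
    half = L / 2.0
    fine_halfwidth = min(fine_halfwidth, half)
    n_fine = max(1, int(round(fine_halfwidth / h_fine)))
    pts = list(np.linspace(0.0, fine_halfwidth, n_fine + 1))
    h = h_fine
    while pts[-1] < half - 1e-9:
        h = min(h * growth, h_max)
        nxt = pts[-1] + h
        if nxt >= half - 0.35 * h:
            nxt = half
        pts.append(min(nxt, half))
    pos = np.array(pts[1:])
    return np.concatenate([-pos[::-1], [0.0], pos])


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def make_box_mesh(xs, ys, zs, region_fn=None) -> TetMesh:
    """Tensor-grid box mesh, 6 Kuhn tets per cube, marked boundary faces.

    The Kuhn split is translation-invariant, so the surface triangulations
    of opposite faces are exact translated copies — the property lateral
    periodicity requires.  ``region_fn(centroids) -> bool`` selects SOLUTE
    elements (default: none).
    """
    xs, ys, zs = (np.asarray(a, dtype=np.float64) for a in (xs, ys, zs))
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corner = {}
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corner[(di, dj, dk)] = vid(i + di, j + dj, k + dk)
    tets = []
    for p in _KUHN_PERMS:
        steps = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in p:
            cur = cur.copy()
            cur[ax] += 1
            steps.append(tuple(cur))
        tets.append(np.stack([corner[s] for s in steps], axis=1))
    tets = np.concatenate(tets)

    box = (xs[-1] - xs[0], ys[-1] - ys[0], zs[-1] - zs[0])
    mesh = TetMesh(vertices, tets, np.full(len(tets), int(Region.SOLVENT)),
                   np.empty((0, 3)), np.empty(0), box=box)
    mesh.orient_positive()
    if region_fn is not None:
        sel = np.asarray(region_fn(mesh.centroids()), dtype=bool)
        mesh.region[sel] = Region.SOLUTE

    faces, counts = mesh.face_counts()
    bnd = faces[counts == 1]
    tol = 1e-6 * max(box)
    fx = mesh.vertices[bnd]
    markers = np.zeros(len(bnd), dtype=np.int64)
    for marker, axis, val in (
        (Boundary.X_MIN, 0, xs[0]), (Boundary.X_MAX, 0, xs[-1]),
        (Boundary.Y_MIN, 1, ys[0]), (Boundary.Y_MAX, 1, ys[-1]),
        (Boundary.BOTTOM, 2, zs[0]), (Boundary.TOP, 2, zs[-1]),
    ):
        on = (np.abs(fx[:, :, axis] - val) <= tol).all(axis=1)
        markers[on] = int(marker)
    if (markers == 0).any():
        raise RuntimeError("unclassified boundary face in box mesh")
    mesh.boundary_faces = bnd
    mesh.boundary_markers = markers
    return mesh


@dataclass(frozen=True)
class ChannelFixtureSpec:
    """Toy membrane-channel system: annular SOLUTE plug around a pore.

    The "protein" is a cylindrical annulus (inner radius ``pore_radius``,
    outer ``wall_radius``, axial half-height ``plug_half_height``) whose
    axis is tilted by ``tilt_deg`` about y; the pore interior stays
    solvent.  ``ring_charges`` point charges of ``ring_charge`` e sit on a
    ring inside the wall.  ``h`` is the target grid spacing.
    """

    box: tuple = (40.0, 40.0, 60.0)
    z1: float = -15.0
    z2: float = 15.0
    pore_radius: float = 5.0
    wall_radius: float = 10.0
    plug_half_height: float = 20.0
    tilt_deg: float = 0.0
    h: float = 1.6
    ring_charges: int = 8
    ring_charge: float = -1.0
    atom_radius: float = 1.5

    def axis(self) -> np.ndarray:
        t = np.deg2rad(self.tilt_deg)
        return np.array([np.sin(t), 0.0, np.cos(t)])


def make_channel_system(spec: ChannelFixtureSpec = ChannelFixtureSpec()) -> tuple[TetMesh, Molecule]:
    """Build the periodic-ready channel mesh and its ring-charge molecule.

    The mesh is labelled SOLUTE/SOLVENT only; insert the slab afterwards
    with :func:`fepb.membrane.label_membrane` and recover the pore with
    :func:`fepb.membrane.detect_pore`.
    """
    lx, ly, lz = spec.box
    d = spec.axis()
    reach = abs(spec.plug_half_height * d[0]) + spec.wall_radius
    if reach > min(lx, ly) / 2.0 - 1e-9:
        raise ValueError("channel plug exits through the box sides")
    if spec.z1 < -lz / 2 or spec.z2 > lz / 2:
        raise ValueError("membrane slab outside the box")

    def axis_coords(L):
        n = max(2, int(round(L / spec.h)))
        return np.linspace(-L / 2, L / 2, n + 1)

    def in_plug(c):
        s = c @ d
        rho = np.linalg.norm(c - np.outer(s, d), axis=1)
        return (rho <= spec.wall_radius) & (rho > spec.pore_radius) & (np.abs(s) <= spec.plug_half_height)

    mesh = make_box_mesh(axis_coords(lx), axis_coords(ly), axis_coords(lz), region_fn=in_plug)

    rc = 0.5 * (spec.pore_radius + spec.wall_radius)
    th = 2.0 * np.pi * np.arange(spec.ring_charges) / max(spec.ring_charges, 1)
    ring = np.column_stack([rc * np.cos(th), rc * np.sin(th), np.zeros_like(th)])
    t = np.deg2rad(spec.tilt_deg)
    rot = np.array([[np.cos(t), 0.0, np.sin(t)], [0.0, 1.0, 0.0], [-np.sin(t), 0.0, np.cos(t)]])
    mol = Molecule(ring @ rot.T, np.full(len(ring), spec.ring_charge),
                   np.full(len(ring), spec.atom_radius))
    return mesh, mol


def make_random_cluster(n_atoms: int, net_charge: float, radius: float, seed: int = 0) -> Molecule:
    """Seeded random charge cluster in a ball (positions uniform, radii 1-2 A).

    Per-atom charges are Gaussian, shifted so they sum to ``net_charge``
    exactly; the same seed reproduces the molecule bit for bit.
    """
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    rng = np.random.default_rng(seed)
    direc = rng.normal(size=(n_atoms, 3))
    direc /= np.linalg.norm(direc, axis=1)[:, None]
    r = radius * rng.uniform(0.0, 1.0, n_atoms) ** (1.0 / 3.0)
    pos = direc * r[:, None]
    q = rng.normal(size=n_atoms)
    q = q - q.mean() + net_charge / n_atoms
    q[0] += net_charge - q.sum()  # exact to the last bit
    radii = rng.uniform(1.0, 2.0, n_atoms)
    return Molecule(pos, q, radii)
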