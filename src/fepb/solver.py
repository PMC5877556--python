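"""P1 finite-element solution of the (nonlinear) Poisson–Boltzmann equation.

The dimensionless potential ``u = e_c * beta * phi`` satisfies

    -div(eps grad u) - C * sum_i n_i z_i exp(-z_i u) * 1_solvent = C * rho_f

with ``C = 4 pi k_e beta`` in Angstrom / elementary-charge / kcal/mol
units, ``n_i`` the bulk number densities (1/A^3) and ``rho_f`` the fixed
point charges.  The ionic term lives only in SOLVENT-labelled elements:
ions are excluded from the solute and from the membrane slab, while a
recognised pore is relabelled SOLVENT and therefore keeps its ions.

Dirichlet data (top/bottom faces, or the whole boundary in non-periodic
mode) is the screened-Coulomb superposition of the fixed charges; lateral
periodicity is imposed by folding slave DOFs onto their masters.

Electrostatic solvation energies come from two solves on the *same* mesh
(solvated vs. uniform-dielectric reference) so the singular numerical
error at the point charges cancels in the difference.  A decomposition
solver (singular + harmonic + regular split) is provided for
cross-validation in non-periodic mode.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .charges import interpolate, locate_points
from .mesh import DIRICHLET_MARKERS, LATERAL_MARKERS, Region, TetMesh
from .molecule import Molecule
from .periodic import PeriodicMap

logger = logging.getLogger("fepb")

__all__ = [
    "K_E", "KB_KCAL", "MOLAR_TO_PER_A3",
    "State", "PhysicsParams", "NewtonConfig", "Solution",
    "assemble_stiffness", "assemble_mass", "dirichlet_values",
    "solve_linear", "solve_pb_newton", "solve_state", "solve_decomposed",
    "NewtonError",
]

# -- unit constants (Angstrom, elementary charge, kcal/mol) -----------------
K_E = 332.0637  # Coulomb constant e_c^2/(4 pi eps0), A * kcal/mol
KB_KCAL = 1.9872041e-3  # Boltzmann constant, kcal/mol/K
MOLAR_TO_PER_A3 = 6.02214076e-4  # mol/L -> particles per A^3


class State(enum.Enum):
    SOLVATED = "solvated"
    REFERENCE = "reference"


class NewtonError(RuntimeError):
    """Newton iteration failed to converge; carries the residual history."""

    def __init__(self, message, history):
        super().__init__(f"{message}; residual history {history}")
        self.history = history


@dataclass(frozen=True)
class PhysicsParams:
    """Dielectrics, ionic species and temperature of one PB problem.

    ``species`` is a sequence of ``(valence, bulk molarity)`` pairs; an
    electroneutral set is required for the nonlinear solve.  The membrane
    slab is ion-free by construction (ionic term only in SOLVENT).
    """

    eps_m: float = 2.0
    eps_s: float = 80.0
    eps_mem: float = 2.0
    species: tuple = ()
    T: float = 298.15

    def __post_init__(self):
        for e in (self.eps_m, self.eps_s, self.eps_mem):
            if e < 1.0:
                raise ValueError("relative dielectrics must be >= 1")
        for z, c in self.species:
            if c < 0:
                raise ValueError("bulk molarities must be non-negative")

    @property
    def kT(self) -> float:
        """Thermal energy, kcal/mol."""
        return KB_KCAL * self.T

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    @property
    def scale(self) -> float:
        """C = 4 pi k_e beta, the source-term scale of the dimensionless PB."""
        return 4.0 * np.pi * K_E * self.beta

    @property
    def densities(self) -> np.ndarray:
        """Bulk number densities per species, 1/A^3."""
        return np.array([c * MOLAR_TO_PER_A3 for _, c in self.species])

    @property
    def valences(self) -> np.ndarray:
        return np.array([z for z, _ in self.species], dtype=np.float64)

    @property
    def ionic_strength(self) -> float:
        """I_s = 1/2 sum c_i z_i^2, molar."""
        return 0.5 * sum(c * z * z for z, c in self.species)

    @property
    def kappa(self) -> float:
        """Inverse Debye length in the solvent, 1/A."""
        k2 = self.scale * (self.densities * self.valences**2).sum() / self.eps_s
        return float(np.sqrt(k2))

    def check_electroneutral(self, tol: float = 1e-10) -> None:
        net = float((self.densities * self.valences).sum())
        tot = float((self.densities * np.abs(self.valences)).sum())
        if tot > 0 and abs(net) > tol * tot:
            raise ValueError("ionic species set is not electroneutral")


@dataclass
class NewtonConfig:
    max_iter: int = 50
    residual_tol: float = 1e-10
    relaxation: float = 0.5
    linear_tol: float = 1e-11

    def __post_init__(self):
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError("relaxation must lie in (0, 1]")


@dataclass
class Solution:
    """Nodal dimensionless potential plus per-atom potentials.

    ``phi_atoms`` is in kcal/mol per elementary charge, interpolated with
    the identical P1 procedure in both states so singular errors cancel in
    energy differences.
    """

    u: np.ndarray
    state: State
    phi_atoms: np.ndarray
    mesh: TetMesh

    def phi_nodal(self, params: PhysicsParams) -> np.ndarray:
        return self.u * params.kT


# ---------------------------------------------------------------------------
# Element matrices
# ---------------------------------------------------------------------------

def p1_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-tet P1 basis gradients (m, 4, 3) and volumes (m,)."""
    v = mesh.tet_vertices()
    e = np.transpose(v[:, 1:] - v[:, :1], (0, 2, 1))  # columns are edges
    det = np.linalg.det(e)
    if (np.abs(det) < 1e-300).any():
        raise ValueError(f"degenerate element at tet {int(np.argmin(np.abs(det)))}")
    inv = np.linalg.inv(e)
    grads = np.empty((mesh.n_tets, 4, 3))
    grads[:, 1:] = inv
    grads[:, 0] = -inv.sum(axis=1)
    return grads, det / 6.0


def eps_per_tet(mesh: TetMesh, params: PhysicsParams, state: State, membrane_on: bool = True) -> np.ndarray:
    if state == State.REFERENCE:
        return np.full(mesh.n_tets, params.eps_m)
    eps = np.where(mesh.region == Region.SOLUTE, params.eps_m, params.eps_s)
    if membrane_on:
        eps = np.where(mesh.region == Region.MEMBRANE, params.eps_mem, eps)
    return eps


def _coo_from_local(mesh: TetMesh, local: np.ndarray) -> sp.csr_matrix:
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    n = mesh.n_vertices
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def assemble_stiffness(
    mesh: TetMesh, params: PhysicsParams, state: State = State.SOLVATED, membrane_on: bool = True,
    eps_override: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Stiffness matrix with element-wise constant dielectric by region.

    Symmetric; rows sum to zero before boundary conditions are applied.
    """
    grads, vols = p1_gradients(mesh)
    eps = eps_per_tet(mesh, params, state, membrane_on) if eps_override is None else eps_override
    local = np.einsum("mid,mjd->mij", grads, grads) * (eps * vols)[:, None, None]
    return _coo_from_local(mesh, local)


def assemble_mass(mesh: TetMesh, weight: np.ndarray | None = None) -> sp.csr_matrix:
    """Consistent P1 mass matrix, optionally with per-tet weights."""
    vols = mesh.volumes() if weight is None else mesh.volumes() * weight
    base = (np.ones((4, 4)) + np.eye(4)) / 20.0
    local = vols[:, None, None] * base
    return _coo_from_local(mesh, local)


# 4-point tetrahedral quadrature (degree 2): barycentric points and weights
_QA, _QB = 0.5854101966249685, 0.1381966011250105
_QPTS = np.full((4, 4), _QB)
np.fill_diagonal(_QPTS, _QA)
_QW = 0.25


# ---------------------------------------------------------------------------
# Boundary data
# ---------------------------------------------------------------------------

def _distances(points: np.ndarray, sources: np.ndarray, box=None) -> np.ndarray:
    """(npoints, nsources) distances, minimum-image in x/y when box given."""
    d = points[:, None, :] - sources[None, :, :]
    if box is not None:
        for ax in (0, 1):
            L = box[ax]
            d[:, :, ax] -= L * np.round(d[:, :, ax] / L)
    return np.linalg.norm(d, axis=2)


def dirichlet_values(
    mol: Molecule, params: PhysicsParams, points, state: State = State.SOLVATED, box=None
) -> np.ndarray:
    """Screened-Coulomb Dirichlet data (dimensionless u) at boundary points.

    ``u(r) = beta * sum_j k_e q_j exp(-kappa |r - r_j|) / (eps |r - r_j|)``
    with ``eps = eps_s`` and the Debye kappa in the solvated state, and
    ``eps = eps_m``, ``kappa = 0`` in the reference state.  With ``box``
    given, distances are minimum-image in x and y (periodic mode).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if len(mol) == 0:
        return np.zeros(len(points))
    d = _distances(points, mol.positions, box=box)
    if (d < 1e-9).any():
        raise ValueError("boundary point coincides with an atom")
    if state == State.SOLVATED:
        eps, kappa = params.eps_s, params.kappa
    else:
        eps, kappa = params.eps_m, 0.0
    contrib = K_E * mol.charges[None, :] / (eps * d)
    if kappa > 0:
        contrib = contrib * np.exp(-kappa * d)
    return params.beta * contrib.sum(axis=1)


@dataclass
class _ReducedSystem:
    """Periodic folding plus Dirichlet bookkeeping for one mesh/bc-mode."""

    P: sp.csr_matrix  # (n_full, n_reduced) expansion
    dir_idx: np.ndarray  # reduced indices carrying Dirichlet data
    dir_vals: np.ndarray
    free_idx: np.ndarray

    @classmethod
    def build(cls, mesh: TetMesh, mol, params, state, bc_mode="dirichlet", pmap: PeriodicMap | None = None):
        n = mesh.n_vertices
        if bc_mode == "periodic":
            if pmap is None:
                raise ValueError("periodic mode requires a PeriodicMap")
            red = pmap.reduced_dof_of_vertex
            nred = pmap.n_reduced
            dir_vertices = mesh.boundary_vertices(DIRICHLET_MARKERS)
            box = mesh.box
        elif bc_mode == "dirichlet":
            red = np.arange(n)
            nred = n
            dir_vertices = mesh.boundary_vertices(DIRICHLET_MARKERS + LATERAL_MARKERS)
            box = None
        else:
            raise ValueError(f"unknown bc_mode {bc_mode!r}")
        P = sp.csr_matrix((np.ones(n), (np.arange(n), red)), shape=(n, nred))
        g = dirichlet_values(mol, params, mesh.vertices[dir_vertices], state, box=box) if mol is not None else np.zeros(len(dir_vertices))
        # Dirichlet wins over periodic: assign per reduced class
        vals = np.zeros(nred)
        vals[red[dir_vertices]] = g
        dir_idx = np.unique(red[dir_vertices])
        free = np.setdiff1d(np.arange(nred), dir_idx, assume_unique=False)
        return cls(P, dir_idx, vals[dir_idx], free)

    def reduce(self, A: sp.csr_matrix, b: np.ndarray):
        Ar = (self.P.T @ A @ self.P).tocsr()
        return Ar, self.P.T @ b

    def expand(self, u_red: np.ndarray) -> np.ndarray:
        return self.P @ u_red

    def full_vector(self) -> np.ndarray:
        u = np.zeros(self.P.shape[1])
        u[self.dir_idx] = self.dir_vals
        return u


def _solve_spd(A: sp.csr_matrix, b: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Solve an SPD sparse system.

    Small systems go through sparse LU; larger ones through conjugate
    gradients after symmetric diagonal (Jacobi) scaling, which tames the
    severe row scaling of strongly graded meshes.
    """
    n = A.shape[0]
    if n == 0:
        return np.zeros(0)
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros(n)
    if n <= 5_000:
        x = spla.spsolve(A.tocsc(), b)
    else:
        s = 1.0 / np.sqrt(A.diagonal())
        S = sp.diags(s)
        Ah = (S @ A @ S).tocsr()
        x, info = spla.cg(Ah, s * b, rtol=tol, atol=0.0, maxiter=50_000)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
        x = s * x
    res = np.linalg.norm(A @ x - b) / bnorm
    if res > max(tol * 100, 1e-8):
        raise RuntimeError(f"linear solve residual {res:.2e} above tolerance")
    return x


def _rhs_vector(mesh: TetMesh, load, params: PhysicsParams) -> np.ndarray:
    if load is None:
        return np.zeros(mesh.n_vertices)
    if isinstance(load, np.ndarray):
        return load
    return params.scale * load.load_vector(mesh)


def solve_linear(
    mesh: TetMesh,
    mol: Molecule,
    load,
    params: PhysicsParams,
    state: State = State.SOLVATED,
    bc_mode: str = "dirichlet",
    pmap: PeriodicMap | None = None,
    linear_tol: float = 1e-10,
    membrane_on: bool = True,
    extra_rhs: np.ndarray | None = None,
) -> Solution:
    """Solve the linear Poisson problem (reference state, or zero salt).

    ``load`` is a charge-treatment object (or a pre-scaled rhs array);
    ``extra_rhs`` adds e.g. an interface-flux load.  Dirichlet rows are
    eliminated symmetrically; in periodic mode slave DOFs are folded first.
    """
    A = assemble_stiffness(mesh, params, state, membrane_on)
    b = _rhs_vector(mesh, load, params)
    if extra_rhs is not None:
        b = b + extra_rhs
    rs = _ReducedSystem.build(mesh, mol, params, state, bc_mode, pmap)
    Ar, br = rs.reduce(A, b)
    u_red = rs.full_vector()
    f, dix = rs.free_idx, rs.dir_idx
    rhs = br[f] - Ar[f][:, dix] @ rs.dir_vals
    u_red[f] = _solve_spd(Ar[f][:, f], rhs, tol=linear_tol)
    u = rs.expand(u_red)
    phi_atoms = interpolate(mesh, u, mol.positions) * params.kT if len(mol) else np.zeros(0)
    return Solution(u=u, state=state, phi_atoms=phi_atoms, mesh=mesh)


def _ionic_terms(mesh, solvent_sel, u_full, params, cap, want_jacobian=True):
    """Mobile-ion residual vector (and Jacobian) with a capped exponential.

    Beyond ``cap`` the Boltzmann exponential continues linearly (a C1
    truncation), and the Jacobian is the exact derivative of that
    truncated residual, so each capped problem is Newton-consistent and
    far less stiff.  Returns ``(vec, mat, max_arg)`` where ``max_arg`` is
    the largest exponent encountered; once ``max_arg < cap`` the truncated
    problem coincides with the true one.
    """
    n = mesh.n_vertices
    dens, val = params.densities, params.valences
    if len(dens) == 0 or dens.sum() == 0 or not solvent_sel.any():
        return np.zeros(n), sp.csr_matrix((n, n)), 0.0
    tets = mesh.tets[solvent_sel]
    vols = mesh.volumes()[solvent_sel]
    uq = u_full[tets] @ _QPTS.T  # (ns, 4 quad points)
    C = params.scale
    res_w = np.zeros_like(uq)
    jac_w = np.zeros_like(uq) if want_jacobian else None
    max_arg = 0.0
    for z, nd in zip(val, dens):
        arg = -z * uq
        max_arg = max(max_arg, float(arg.max()))
        clipped = arg > cap
        ecap = np.exp(cap)
        e = np.where(clipped, ecap * (1.0 + (arg - cap)), np.exp(np.minimum(arg, cap)))
        res_w += C * nd * z * e
        if want_jacobian:
            de = np.where(clipped, ecap, e)
            jac_w += C * nd * z * z * de
    vec = np.zeros(n)
    np.add.at(vec, tets, (_QW * vols)[:, None] * (res_w @ _QPTS))
    if not want_jacobian:
        return vec, None, max_arg
    local = np.einsum("mq,qi,qj->mij", (_QW * vols)[:, None] * jac_w, _QPTS, _QPTS)
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    mat = sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return vec, mat, max_arg


def solve_pb_newton(
    mesh: TetMesh,
    mol: Molecule,
    load,
    params: PhysicsParams,
    cfg: NewtonConfig | None = None,
    bc_mode: str = "dirichlet",
    pmap: PeriodicMap | None = None,
    membrane_on: bool = True,
    extra_rhs: np.ndarray | None = None,
) -> Solution:
    """Damped Newton solution of the nonlinear PB equation (solvated state).

    The ionic integrals use 4-point tetrahedral quadrature with the current
    iterate interpolated at the quadrature points, and extend only over
    SOLVENT-labelled elements.  The relaxation factor starts at
    ``cfg.relaxation`` and doubles toward 1 whenever the residual drops.
    """
    cfg = cfg or NewtonConfig()
    params.check_electroneutral()
    state = State.SOLVATED
    A = assemble_stiffness(mesh, params, state, membrane_on)
    b = _rhs_vector(mesh, load, params)
    if extra_rhs is not None:
        b = b + extra_rhs
    rs = _ReducedSystem.build(mesh, mol, params, state, bc_mode, pmap)
    Ar, br = rs.reduce(A, b)
    f, dix = rs.free_idx, rs.dir_idx
    Aff = Ar[f][:, f]
    Afd = Ar[f][:, dix]
    solvent_sel = mesh.region == Region.SOLVENT
    bf = br[f] - Afd @ rs.dir_vals
    scale_ref = max(np.linalg.norm(bf), 1.0)

    def residual(uf, cap, want_jacobian):
        u_red = rs.full_vector()
        u_red[f] = uf
        vec, mat, max_arg = _ionic_terms(mesh, solvent_sel, rs.expand(u_red), params, cap,
                                         want_jacobian)
        F = Aff @ uf - (rs.P.T @ vec)[f] - bf
        return F, mat, max_arg

    uf = np.zeros(len(f))  # interior start; Dirichlet held in rs
    history = []
    cap = 4.0
    total_it = 0
    while True:  # continuation in the exponent cap
        converged = False
        omega = cfg.relaxation
        F, ionmat, max_arg = residual(uf, cap, True)
        rnorm = np.linalg.norm(F)
        for _ in range(cfg.max_iter):
            total_it += 1
            history.append(float(rnorm))
            logger.debug("newton cap %.0f iter %d residual %.3e", cap, total_it, rnorm)
            if rnorm <= cfg.residual_tol * scale_ref:
                converged = True
                break
            imr = (rs.P.T @ ionmat @ rs.P).tocsr()
            J = Aff + imr[f][:, f]
            delta = _solve_spd(J, -F, tol=cfg.linear_tol)
            # backtracking: accept only a residual decrease
            omega = min(1.0, 2.0 * omega)
            while True:
                F_new, _, _ = residual(uf + omega * delta, cap, False)
                if np.linalg.norm(F_new) < rnorm or omega < 1e-8:
                    break
                omega *= 0.5
            if omega < 1e-8:
                raise NewtonError("Newton line search stalled", history)
            uf = uf + omega * delta
            F, ionmat, max_arg = residual(uf, cap, True)
            rnorm = np.linalg.norm(F)
        if not converged:
            raise NewtonError(f"Newton did not converge in {cfg.max_iter} iterations "
                              f"at cap {cap}", history)
        if max_arg <= 0.999 * cap:
            break  # cap inactive: the truncated problem is the true problem
        if cap >= 700.0:
            raise NewtonError("Boltzmann factors overflow (|z u| >= 700)", history)
        cap = min(2.0 * cap, 700.0)

    u_red = rs.full_vector()
    u_red[f] = uf
    u = rs.expand(u_red)
    phi_atoms = interpolate(mesh, u, mol.positions) * params.kT if len(mol) else np.zeros(0)
    return Solution(u=u, state=state, phi_atoms=phi_atoms, mesh=mesh)


def solve_state(
    mesh: TetMesh,
    mol: Molecule,
    load,
    params: PhysicsParams,
    state: State,
    bc_mode: str = "dirichlet",
    pmap: PeriodicMap | None = None,
    cfg: NewtonConfig | None = None,
    membrane_on: bool = True,
) -> Solution:
    """Dispatch: reference or salt-free problems are linear, else Newton."""
    if state == State.REFERENCE or params.ionic_strength == 0.0:
        tol = (cfg or NewtonConfig()).linear_tol
        return solve_linear(mesh, mol, load, params, state, bc_mode, pmap,
                            linear_tol=tol, membrane_on=membrane_on)
    return solve_pb_newton(mesh, mol, load, params, cfg, bc_mode, pmap, membrane_on)


# ---------------------------------------------------------------------------
# Decomposition (singular G + harmonic H + regular phi_r) cross-check
# ---------------------------------------------------------------------------

@dataclass
class DecomposedResult:
    H_atoms: np.ndarray  # kcal/mol/e at the atoms
    phi_r: np.ndarray  # nodal dimensionless regular component
    energy: float  # kcal/mol


def _coulomb_u(mol: Molecule, params: PhysicsParams, points: np.ndarray) -> np.ndarray:
    d = _distances(np.atleast_2d(points), mol.positions)
    return params.beta * (K_E * mol.charges[None, :] / (params.eps_m * d)).sum(axis=1)


def _coulomb_grad_u(mol: Molecule, params: PhysicsParams, points: np.ndarray) -> np.ndarray:
    diff = np.atleast_2d(points)[:, None, :] - mol.positions[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    w = -params.beta * K_E * mol.charges[None, :] / (params.eps_m * d**3)
    return (w[..., None] * diff).sum(axis=1)


def solve_decomposed(
    mesh: TetMesh,
    mol: Molecule,
    params: PhysicsParams,
    cfg: NewtonConfig | None = None,
    membrane_on: bool = True,
    bc_mode: str = "dirichlet",
) -> DecomposedResult:
    """Decomposition solve: u = G + H + phi_r inside the solute.

    ``G`` is the analytic Coulomb potential of the fixed charges in the
    solute dielectric; ``H`` solves the Laplace problem on the solute
    sub-mesh with ``H = -G`` on the solute boundary; ``phi_r`` solves the
    regular PB problem driven by the interface flux of ``G + H``.  The
    electrostatic solvation energy is ``1/2 sum q_i (H_i + phi_r,i)`` —
    smooth at the charges, no reference solve needed.  Non-periodic
    Dirichlet mode only.
    """
    cfg = cfg or NewtonConfig()
    if bc_mode != "dirichlet":
        raise NotImplementedError(
            "the decomposition method supports non-periodic (Dirichlet) mode only: "
            "net solute charge breaks the periodic singular component"
        )
    if len(mol) == 0 or not np.any(mol.charges):
        return DecomposedResult(np.zeros(len(mol)), np.zeros(mesh.n_vertices), 0.0)

    # -- solute sub-mesh
    sel = np.nonzero(mesh.region == Region.SOLUTE)[0]
    if len(sel) == 0:
        raise ValueError("mesh has no SOLUTE region")
    tets = mesh.tets[sel]
    used = np.unique(tets)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub_tets = remap[tets]
    sub_verts = mesh.vertices[used]

    faces = sub_tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
    sfaces = np.sort(faces, axis=1)
    uniq, first, counts = np.unique(sfaces, axis=0, return_index=True, return_counts=True)
    bnd_face_rows = first[counts == 1]  # row into `faces`
    bnd_faces = faces[bnd_face_rows]
    owner_tet = bnd_face_rows // 4  # index into sel
    opposite_local = bnd_face_rows % 4

    # -- harmonic component H on the sub-mesh (dimensionless)
    sub_mesh = TetMesh(sub_verts, sub_tets, np.full(len(sub_tets), int(Region.SOLUTE)),
                       bnd_faces, np.zeros(len(bnd_faces)))
    sub_mesh.orient_positive()
    A = assemble_stiffness(sub_mesh, params, State.REFERENCE, eps_override=np.ones(len(sub_tets)))
    dir_v = np.unique(bnd_faces)
    g = -_coulomb_u(mol, params, sub_verts[dir_v])
    free = np.setdiff1d(np.arange(len(sub_verts)), dir_v)
    H = np.zeros(len(sub_verts))
    H[dir_v] = g
    H[free] = _solve_spd(A[free][:, free], -A[free][:, dir_v] @ g, tol=cfg.linear_tol)
    H_atoms_u = interpolate(sub_mesh, H, mol.positions)

    # -- interface flux load for phi_r: -int_Gamma eps_m d_n(G+H) v ds
    gradsH, _ = p1_gradients(sub_mesh)
    gradH_tet = np.einsum("mi,mid->md", H[sub_mesh.tets[owner_tet]], gradsH[owner_tet])
    tri = sub_verts[bnd_faces]  # (k,3,3)
    e1, e2 = tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    nvec = np.cross(e1, e2)
    area = 0.5 * np.linalg.norm(nvec, axis=1)
    nhat = nvec / np.linalg.norm(nvec, axis=1)[:, None]
    # orient outward from the solute: away from the opposite (interior) vertex
    opp = sub_verts[sub_mesh.tets[owner_tet, opposite_local]]
    flip = np.einsum("kd,kd->k", nhat, tri[:, 0] - opp) < 0
    nhat[flip] *= -1.0
    mids = 0.5 * (tri + np.roll(tri, -1, axis=1))  # m01, m12, m20
    gradG = _coulomb_grad_u(mol, params, mids.reshape(-1, 3)).reshape(-1, 3, 3)
    fq = params.eps_m * np.einsum("kqd,kd->kq", gradG + gradH_tet[:, None, :], nhat)
    # edge-midpoint rule: vertex 0 sees midpoints m01 and m20 with weight 1/2
    vert_flux = 0.5 * (fq + np.roll(fq, 1, axis=1))  # (k,3) per local vertex
    load = np.zeros(mesh.n_vertices)
    np.add.at(load, used[bnd_faces], -(area / 3.0)[:, None] * vert_flux)

    # -- regular component phi_r on the full mesh
    if params.ionic_strength > 0:
        sol = solve_pb_newton(mesh, mol, None, params, cfg, "dirichlet",
                              membrane_on=membrane_on, extra_rhs=load)
    else:
        sol = solve_linear(mesh, mol, None, params, State.SOLVATED, "dirichlet",
                           linear_tol=cfg.linear_tol, membrane_on=membrane_on, extra_rhs=load)
    phi_r_atoms_u = interpolate(mesh, sol.u, mol.positions)

    energy = 0.5 * float(np.dot(mol.charges, (H_atoms_u + phi_r_atoms_u))) * params.kT
    return DecomposedResult(H_atoms=H_atoms_u * params.kT, phi_r=sol.u, energy=energy)
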