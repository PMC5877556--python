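"""FEM assembly, boundary data, linear/Newton/decomposed PB solves."""

import numpy as np
import pytest
import scipy.sparse as sp

from fepb import (
    Molecule,
    NewtonConfig,
    PhysicsParams,
    State,
    assemble_stiffness,
    dirichlet_values,
    direct_load,
    make_box_mesh,
    make_random_cluster,
    solve_decomposed,
    solve_linear,
    solve_pb_newton,
)
from fepb.energy import born_analytic
from fepb.fixtures import BornFixtureSpec, graded_axis, make_born_mesh
from fepb.solver import K_E, _ReducedSystem, _ionic_terms, _solve_spd

PARAMS = PhysicsParams(eps_m=2.0, eps_s=80.0)
SALT_01 = PhysicsParams(eps_m=2.0, eps_s=80.0, species=((1.0, 0.1), (-1.0, 0.1)))

# hand-integrated local stiffness of the unit right tet, eps = 1
K_UNIT_RIGHT = np.array(
    [[3.0, -1.0, -1.0, -1.0], [-1.0, 1.0, 0.0, 0.0], [-1.0, 0.0, 1.0, 0.0], [-1.0, 0.0, 0.0, 1.0]]
) / 6.0


@pytest.fixture(scope="module")
def small_cluster_system():
    ax = graded_axis(30.0, 8.0, 1.5, h_max=5.0)
    mesh = make_box_mesh(ax, ax, ax, region_fn=lambda c: np.abs(c).max(axis=1) <= 6.0)
    mol = make_random_cluster(10, -2.0, 3.0, seed=3)
    return mesh, mol


class TestStiffness:
    def test_unit_right_tet_matches_hand_integration(self, unit_right_tet):
        A = assemble_stiffness(unit_right_tet, PhysicsParams(eps_m=1.0, eps_s=1.0), State.REFERENCE,
                               eps_override=np.array([1.0]))
        np.testing.assert_allclose(A.toarray(), K_UNIT_RIGHT, atol=1e-14)

    def test_rows_sum_to_zero_and_symmetric(self, coarse_born_mesh):
        A = assemble_stiffness(coarse_born_mesh, PARAMS, State.SOLVATED)
        assert np.abs(A.sum(axis=1)).max() < 1e-9
        assert abs(A - A.T).max() < 1e-10

    def test_dielectric_scaling_is_linear(self, unit_right_tet):
        A1 = assemble_stiffness(unit_right_tet, PARAMS, State.SOLVATED, eps_override=np.array([1.0]))
        A2 = assemble_stiffness(unit_right_tet, PARAMS, State.SOLVATED, eps_override=np.array([2.0]))
        np.testing.assert_allclose(A2.toarray(), 2.0 * A1.toarray(), atol=1e-14)

    def test_reference_state_ignores_region_labels(self, coarse_born_mesh):
        A = assemble_stiffness(coarse_born_mesh, PARAMS, State.REFERENCE)
        A_scaled = assemble_stiffness(
            coarse_born_mesh, PARAMS, State.REFERENCE,
            eps_override=np.full(coarse_born_mesh.n_tets, PARAMS.eps_m),
        )
        assert abs(A - A_scaled).max() < 1e-12


class TestDirichletValues:
    def test_zero_charges_give_zero(self, born_ion):
        q0 = Molecule(born_ion.positions, [0.0], [1.0])
        u = dirichlet_values(q0, PARAMS, [[10.0, 0.0, 0.0]])
        assert u[0] == 0.0

    def test_coulomb_limit_halves_with_distance(self, born_ion):
        pts = [[4.0, 0.0, 0.0], [8.0, 0.0, 0.0]]
        u = dirichlet_values(born_ion, PARAMS, pts, State.SOLVATED)
        expect = PARAMS.beta * K_E / (PARAMS.eps_s * 4.0)
        assert np.isclose(u[0], expect)
        assert np.isclose(u[0], 2 * u[1])

    def test_screening_factor_is_exponential(self, born_ion):
        rng = np.random.default_rng(0)
        d = rng.uniform(3.0, 30.0, 8)
        pts = np.column_stack([d, np.zeros(8), np.zeros(8)])
        u0 = dirichlet_values(born_ion, PARAMS, pts, State.SOLVATED)
        us = dirichlet_values(born_ion, SALT_01, pts, State.SOLVATED)
        np.testing.assert_allclose(us, u0 * np.exp(-SALT_01.kappa * d), rtol=1e-12)

    def test_debye_length_at_physiological_salt(self):
        # 0.1 M 1:1 salt in water at 298 K screens over roughly 9.6-9.8 A
        assert np.isclose(1.0 / SALT_01.kappa, 9.7, atol=0.15)

    def test_point_on_atom_raises(self, born_ion):
        with pytest.raises(ValueError):
            dirichlet_values(born_ion, PARAMS, [[0.0, 0.0, 0.0]])


class TestSolveLinear:
    def test_zero_load_zero_bc_gives_zero(self, small_cluster_system):
        mesh, _ = small_cluster_system
        mol = Molecule([[0.0, 0.0, 0.0]], [0.0], [1.0])
        sol = solve_linear(mesh, mol, direct_load(mol, mesh), PARAMS, State.SOLVATED)
        assert np.abs(sol.u).max() == 0.0

    def test_doubling_charges_doubles_potential(self, small_cluster_system):
        mesh, mol = small_cluster_system
        s1 = solve_linear(mesh, mol, direct_load(mol, mesh), PARAMS, State.SOLVATED)
        mol2 = Molecule(mol.positions, 2 * mol.charges, mol.radii)
        s2 = solve_linear(mesh, mol2, direct_load(mol2, mesh), PARAMS, State.SOLVATED)
        np.testing.assert_allclose(s2.u, 2 * s1.u, atol=5e-7 * np.abs(s1.u).max())

    def test_reduced_system_symmetric_positive(self, small_cluster_system):
        mesh, mol = small_cluster_system
        A = assemble_stiffness(mesh, PARAMS, State.SOLVATED)
        rs = _ReducedSystem.build(mesh, mol, PARAMS, State.SOLVATED, "dirichlet")
        f = rs.free_idx
        Aff = (rs.P.T @ A @ rs.P)[f][:, f]
        assert abs(Aff - Aff.T).max() < 1e-10
        rng = np.random.default_rng(1)
        for _ in range(3):
            x = rng.normal(size=Aff.shape[0])
            assert x @ (Aff @ x) > 0


class TestNewton:
    def test_zero_salt_newton_equals_linear(self, small_cluster_system):
        mesh, mol = small_cluster_system
        load = direct_load(mol, mesh)
        lin = solve_linear(mesh, mol, load, PARAMS, State.SOLVATED, linear_tol=1e-12)
        new = solve_pb_newton(mesh, mol, load, PARAMS, NewtonConfig(linear_tol=1e-12))
        np.testing.assert_allclose(new.u, lin.u, atol=1e-10 * max(1.0, np.abs(lin.u).max()))

    def test_no_charge_symmetric_salt_stays_zero(self, small_cluster_system):
        mesh, _ = small_cluster_system
        mol = Molecule([[0.0, 0.0, 0.0]], [0.0], [1.0])
        sol = solve_pb_newton(mesh, mol, direct_load(mol, mesh), SALT_01)
        assert np.abs(sol.u).max() < 1e-12

    def test_electroneutrality_required(self, small_cluster_system):
        mesh, mol = small_cluster_system
        bad = PhysicsParams(species=((1.0, 0.1),))
        with pytest.raises(ValueError, match="electroneutral"):
            solve_pb_newton(mesh, mol, direct_load(mol, mesh), bad)

    def test_small_charge_matches_linearized_pb_to_first_order(self, small_cluster_system):
        """Deviation from the LPB oracle scales as the charge cubed."""
        mesh, mol = small_cluster_system
        devs = []
        for scale in (0.02, 0.01):
            m = Molecule(mol.positions, mol.charges * scale, mol.radii)
            load = direct_load(m, mesh)
            npb = solve_pb_newton(mesh, m, load, SALT_01,
                                  NewtonConfig(residual_tol=1e-12, linear_tol=1e-13))
            # independent linearized-PB solve: Jacobian at u = 0
            A = assemble_stiffness(mesh, SALT_01, State.SOLVATED)
            vec0, mat0, _ = _ionic_terms(mesh, mesh.region == 2, np.zeros(mesh.n_vertices),
                                         SALT_01, 700.0, True)
            rs = _ReducedSystem.build(mesh, m, SALT_01, State.SOLVATED, "dirichlet")
            b = SALT_01.scale * load.load_vector(mesh) + vec0
            Ar, br = (rs.P.T @ (A + mat0) @ rs.P).tocsr(), rs.P.T @ b
            f, dix = rs.free_idx, rs.dir_idx
            ur = rs.full_vector()
            ur[f] = _solve_spd(Ar[f][:, f], br[f] - Ar[f][:, dix] @ rs.dir_vals, tol=1e-13)
            devs.append(np.abs(npb.u - rs.expand(ur)).max())
        ratio = devs[0] / devs[1]
        assert 6.0 < ratio < 10.5  # cubic scaling of the first nonlinear correction


class TestDecomposed:
    def test_born_fixture_matches_analytic_closely(self, born_ion):
        mesh = make_born_mesh(BornFixtureSpec(subdiv=1, n_shells_solute=2, n_shells_solvent=8))
        dec = solve_decomposed(mesh, born_ion, PARAMS)
        exact = born_analytic(1.0, 1.0, 2.0, 80.0)
        assert abs((dec.energy - exact) / exact) < 0.005  # smooth: no singular error
        # H + phi_r is finite and smooth at the charge
        assert np.isfinite(dec.H_atoms).all()

    def test_zero_charges_give_zero(self, coarse_born_mesh):
        mol = Molecule([[0.0, 0.0, 0.0]], [0.0], [1.0])
        dec = solve_decomposed(coarse_born_mesh, mol, PARAMS)
        assert dec.energy == 0.0
        assert np.abs(dec.phi_r).max() == 0.0

    def test_periodic_mode_is_rejected(self, coarse_born_mesh, born_ion):
        with pytest.raises(NotImplementedError, match="periodic"):
            solve_decomposed(coarse_born_mesh, born_ion, PARAMS, bc_mode="periodic")
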