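"""Singular fixed-charge treatments: direct, vertex, average, weighted."""

import numpy as np
import pytest

from fepb import (
    Molecule,
    assign_average,
    assign_vertex_on_charge,
    assign_weighted,
    barycentric_coords,
    direct_load,
    make_box_mesh,
    make_random_cluster,
)
from fepb.charges import locate_points, vertex_patch_volumes
from fepb.fixtures import BornFixtureSpec, make_born_mesh


@pytest.fixture(scope="module")
def box_mesh():
    ax = np.linspace(-6.0, 6.0, 13)  # uniform unit spacing, all SOLUTE
    return make_box_mesh(ax, ax, ax, region_fn=lambda c: np.full(len(c), True))


@pytest.fixture(scope="module")
def born_mesh():
    return make_born_mesh(BornFixtureSpec(subdiv=1, n_shells_solute=3, n_shells_solvent=6))


class TestBarycentric:
    def test_vertices_and_barycenter(self, unit_right_tet):
        v = unit_right_tet.tet_vertices()[0]
        for i in range(4):
            lam = barycentric_coords(v, v[i])
            expect = np.zeros(4)
            expect[i] = 1.0
            np.testing.assert_allclose(lam, expect, atol=1e-14)
        np.testing.assert_allclose(barycentric_coords(v, v.mean(axis=0)), 0.25, atol=1e-14)

    def test_volume_ratio_equals_linear_reconstruction(self, unit_right_tet):
        """Sub-tet volume ratios solve the 4x4 linear reconstruction system."""
        rng = np.random.default_rng(42)
        v = unit_right_tet.tet_vertices()[0]
        A = np.vstack([np.ones(4), v.T])  # rows: sum-to-one, x, y, z
        for _ in range(20):
            w = rng.dirichlet(np.ones(4))
            p = w @ v
            lam = barycentric_coords(v, p)
            oracle = np.linalg.solve(A, np.concatenate([[1.0], p]))
            np.testing.assert_allclose(lam, oracle, atol=1e-12)
            assert abs(lam.sum() - 1.0) < 1e-12

    def test_degenerate_tet_raises(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            barycentric_coords(flat, [0.3, 0.3, 0.0])


class TestDirectLoad:
    def test_charge_on_vertex_loads_that_vertex_only(self, box_mesh):
        mol = Molecule([[0.0, 0.0, 0.0]], [2.5], [1.0])
        b = direct_load(mol, box_mesh).values
        vid = int(np.argmin(np.linalg.norm(box_mesh.vertices, axis=1)))
        assert np.isclose(b[vid], 2.5)
        assert np.isclose(np.abs(b).sum(), 2.5)

    def test_charge_at_barycenter_splits_equally(self, box_mesh):
        tet = box_mesh.tets[0]
        p = box_mesh.vertices[tet].mean(axis=0)
        b = direct_load(Molecule([p], [1.0], [1.0]), box_mesh).values
        np.testing.assert_allclose(b[tet], 0.25, atol=1e-12)

    def test_atom_outside_solute_raises(self, born_mesh):
        mol = Molecule([[0.0, 0.0, 5.0]], [1.0], [1.0])  # in the solvent shell
        with pytest.raises(ValueError, match="solute"):
            direct_load(mol, born_mesh)


class TestAssignments:
    def test_vertex_on_charge_coefficient_formula(self, box_mesh):
        mol = Molecule([[0.0, 0.0, 0.0]], [1.0], [1.0])
        dens = assign_vertex_on_charge(mol, box_mesh)
        vid = int(np.argmin(np.linalg.norm(box_mesh.vertices, axis=1)))
        patch = vertex_patch_volumes(box_mesh)[vid]
        assert np.isclose(dens.coefficients[vid], 4.0 / patch)
        assert np.isclose(dens.total_charge(box_mesh), 1.0)

    def test_vertex_on_charge_rejects_offset_atom(self, box_mesh):
        with pytest.raises(ValueError, match="vertex"):
            assign_vertex_on_charge(Molecule([[0.3, 0.0, 0.0]], [1.0], [1.0]), box_mesh)

    def test_two_vertex_charges_superpose(self, box_mesh):
        mol = Molecule([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], [1.0, 2.0], [1.0, 1.0])
        dens = assign_vertex_on_charge(mol, box_mesh)
        assert np.isclose(dens.total_charge(box_mesh), 3.0)

    def test_average_single_vertex_takes_all(self, box_mesh):
        mol = Molecule([[0.0, 0.0, 0.0]], [1.5], [1.0])
        dens = assign_average(mol, box_mesh, r_cut=0.5)
        assert np.isclose(dens.total_charge(box_mesh), 1.5)
        assert (dens.coefficients != 0).sum() == 1

    def test_average_equal_patch_vertices_get_equal_coefficients(self, box_mesh):
        mol = Molecule([[0.5, 0.5, 0.5]], [1.0], [1.0])  # cube centre, 8 interior vertices
        dens = assign_average(mol, box_mesh, r_cut=1.0)
        nz = dens.coefficients[dens.coefficients != 0]
        assert len(nz) == 8
        np.testing.assert_allclose(nz, nz[0])

    def test_average_no_vertex_in_reach_raises(self, box_mesh):
        with pytest.raises(ValueError, match="r_cut"):
            assign_average(Molecule([[0.5, 0.5, 0.5]], [1.0], [1.0]), box_mesh, r_cut=0.1)

    def test_weighted_on_vertex_reduces_to_vertex_on_charge(self, box_mesh):
        mol = Molecule([[1.0, -1.0, 2.0]], [1.0], [1.0])
        w = assign_weighted(mol, box_mesh)
        v = assign_vertex_on_charge(mol, box_mesh)
        np.testing.assert_allclose(w.coefficients, v.coefficients, atol=1e-9)

    def test_weighted_interior_barycenter_equal_coefficients(self, box_mesh):
        tid, _ = locate_points(box_mesh, [[0.4, 0.3, 0.2]])
        tet = box_mesh.tets[tid[0]]
        p = box_mesh.vertices[tet].mean(axis=0)
        dens = assign_weighted(Molecule([p], [1.0], [1.0]), box_mesh)
        nz = dens.coefficients[tet]
        np.testing.assert_allclose(nz, nz[0], rtol=1e-12)


class TestConservation:
    @pytest.mark.parametrize("method", ["direct", "average", "weighted"])
    def test_hundred_random_charges_integrate_exactly(self, born_mesh, method):
        """Global invariance: assigned charge equals molecular net charge."""
        from fepb.energy import CHARGE_METHODS

        mol = make_random_cluster(100, -7.0, 0.8, seed=13)
        load = CHARGE_METHODS[method](mol, born_mesh)
        total = load.total_charge(born_mesh)
        assert abs(total - mol.net_charge) <= 1e-12 * abs(mol.net_charge)
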