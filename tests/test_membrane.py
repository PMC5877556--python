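"""Membrane slab labelling, pore recognition and tilt rotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fepb import (
    ChannelFixtureSpec,
    MembraneSpec,
    PoreDetectionError,
    Region,
    detect_pore,
    fill_pore_partial,
    label_membrane,
    make_box_mesh,
    make_channel_system,
    make_random_cluster,
    relabel_pore,
    rotate_molecule,
)

SLAB = MembraneSpec(-15.0, 15.0, 2.0)


@pytest.fixture(scope="module")
def channel():
    spec = ChannelFixtureSpec(h=2.0)
    mesh, mol = make_channel_system(spec)
    return spec, mesh, mol


@pytest.fixture(scope="module")
def labelled(channel):
    spec, mesh, _ = channel
    return label_membrane(mesh, SLAB)


def _geometric_pore(mesh, spec, slab):
    c = mesh.centroids()
    d = spec.axis()
    s = c @ d
    rho = np.linalg.norm(c - np.outer(s, d), axis=1)
    return set(
        np.nonzero((rho <= spec.pore_radius) & (c[:, 2] >= slab.z1) & (c[:, 2] <= slab.z2))[0].tolist()
    )


class TestLabelMembrane:
    def test_slab_below_all_tets_is_identity(self, channel):
        _, mesh, _ = channel
        # inside the box but below every element centroid (lowest is -29.5)
        out = label_membrane(mesh, MembraneSpec(-29.99, -29.6, 2.0))
        np.testing.assert_array_equal(out.region, mesh.region)

    def test_solvent_only_box_volume_fraction(self):
        ax = np.linspace(-20, 20, 17)
        az = np.linspace(-30, 30, 25)
        mesh = make_box_mesh(ax, ax, az)
        out = label_membrane(mesh, SLAB)
        frac = out.region_volume(Region.MEMBRANE) / out.volumes().sum()
        assert np.isclose(frac, 30.0 / 60.0, atol=1e-12)

    def test_solute_never_relabelled(self, channel, labelled):
        _, mesh, _ = channel
        solute = mesh.region == Region.SOLUTE
        assert (labelled.region[solute] == Region.SOLUTE).all()

    def test_slab_outside_box_raises(self, channel):
        _, mesh, _ = channel
        with pytest.raises(ValueError):
            label_membrane(mesh, MembraneSpec(-100.0, 100.0, 2.0))


class TestDetectPore:
    def test_straight_pore_matches_geometric_oracle(self, channel, labelled):
        spec, _, _ = channel
        pore = set(detect_pore(labelled, SLAB, seed="auto").tolist())
        assert pore == _geometric_pore(labelled, spec, SLAB)

    def test_label_then_detect_restores_solvent_connectivity(self, channel, labelled):
        spec, mesh, _ = channel
        restored = relabel_pore(labelled, detect_pore(labelled, SLAB, seed="auto"))
        # everything that was solvent inside the pore is solvent again
        pore = _geometric_pore(mesh, spec, SLAB)
        assert all(restored.region[i] == Region.SOLVENT for i in pore)

    def test_seed_choice_does_not_change_component(self, labelled):
        a = detect_pore(labelled, SLAB, seed=(0.0, 0.0, 0.0))
        b = detect_pore(labelled, SLAB, seed=(1.0, -1.5, 9.0))
        np.testing.assert_array_equal(np.sort(a), np.sort(b))

    def test_tilted_channel_is_still_found(self):
        spec = ChannelFixtureSpec(h=2.0, tilt_deg=20.0)
        mesh, _ = make_channel_system(spec)
        lab = label_membrane(mesh, SLAB)
        pore = set(detect_pore(lab, SLAB, seed="auto").tolist())
        oracle = _geometric_pore(lab, spec, SLAB)
        # staircase wall: allow mismatches only among wall-adjacent elements
        mismatch = pore ^ oracle
        c = lab.centroids()
        d = spec.axis()
        rho = np.linalg.norm(c - np.outer(c @ d, d), axis=1)
        assert all(abs(rho[i] - spec.pore_radius) < 2.0 * spec.h for i in mismatch)

    def test_bare_slab_seed_is_rejected(self):
        ax = np.linspace(-20, 20, 17)
        az = np.linspace(-30, 30, 25)
        lab = label_membrane(make_box_mesh(ax, ax, az), SLAB)
        with pytest.raises(PoreDetectionError):
            detect_pore(lab, SLAB, seed=(0.0, 0.0, 0.0))

    def test_seed_in_solute_is_rejected(self, labelled):
        with pytest.raises(PoreDetectionError):
            detect_pore(labelled, SLAB, seed=(7.5, 0.0, 0.0))


class TestFillPorePartial:
    def test_identity_full_and_errors(self, channel, labelled):
        pore = detect_pore(labelled, SLAB, seed="auto")
        opened = relabel_pore(labelled, pore)
        same = fill_pore_partial(opened, pore, 0.0, SLAB)
        np.testing.assert_array_equal(same.region, opened.region)
        full = fill_pore_partial(opened, pore, SLAB.thickness, SLAB)
        assert (full.region[pore] == Region.MEMBRANE).all()
        half = fill_pore_partial(opened, pore, 15.0, SLAB)
        n_half = (half.region[pore] == Region.MEMBRANE).sum()
        assert 0 < n_half < len(pore)
        for bad in (-1.0, SLAB.thickness + 1.0):
            with pytest.raises(ValueError):
                fill_pore_partial(opened, pore, bad, SLAB)


class TestRotateMolecule:
    def test_zero_and_full_turn_are_identity(self):
        mol = make_random_cluster(12, 1.0, 3.0, seed=5)
        np.testing.assert_allclose(rotate_molecule(mol, 0.0).positions, mol.positions, atol=1e-12)
        np.testing.assert_allclose(rotate_molecule(mol, 360.0).positions, mol.positions, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(-180.0, 180.0), st.floats(0.0, 2 * np.pi), st.integers(0, 2**31 - 1))
    def test_rigid_rotation_preserves_distances(self, angle, phi, seed):
        mol = make_random_cluster(8, 0.0, 2.0, seed=seed % 1000)
        rot = rotate_molecule(mol, angle, axis=(np.cos(phi), np.sin(phi), 0.0))
        d0 = np.linalg.norm(mol.positions[:, None] - mol.positions[None], axis=2)
        d1 = np.linalg.norm(rot.positions[:, None] - rot.positions[None], axis=2)
        np.testing.assert_allclose(d1, d0, atol=1e-11)
        np.testing.assert_array_equal(rot.charges, mol.charges)

    def test_axis_must_lie_in_membrane_plane(self):
        mol = make_random_cluster(3, 0.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            rotate_molecule(mol, 10.0, axis=(0.0, 0.0, 1.0))
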