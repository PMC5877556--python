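"""Electrostatic, non-polar and total solvation energies.

The electrostatic part is the per-atom potential difference between the
solvated and reference solves on the same mesh:

    dG_ele = 1/2 sum_i q_i (phi_i,sys - phi_i,ref)        [kcal/mol]

The non-polar part follows the membrane-aware surface-area model

    dG_np = gamma * sum_i S(z_i) * SA_i

with a piecewise-linear depth profile S(z) that drops from 1 in water to
``s_core`` inside the slab over ramps of width ``w``.  The analytic Born
ion provides the accuracy oracle for the electrostatic solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charges import assign_average, assign_vertex_on_charge, assign_weighted, direct_load
from .membrane import MembraneSpec, rotate_molecule
from .molecule import Molecule, compute_sasa
from .solver import K_E, Solution, State, solve_state

__all__ = [
    "born_analytic",
    "relative_error_percent",
    "electrostatic_energy",
    "electrostatic_solvation",
    "CHARGE_METHODS",
    "SurfaceTensionProfile",
    "EnergyReport",
    "nonpolar_energy",
    "tilt_scan",
]

#: name -> factory for the singular-charge treatments
CHARGE_METHODS = {
    "direct": direct_load,
    "vertex": assign_vertex_on_charge,
    "average": assign_average,
    "weighted": assign_weighted,
}


def born_analytic(q: float, r: float, eps_m: float, eps_s: float) -> float:
    """Analytic electrostatic solvation energy of a Born ion, kcal/mol.

    ``(k_e q^2 / 2r) (1/eps_s - 1/eps_m)`` — negative (favourable) for
    ``eps_s > eps_m``.  With q = 1 e, r = 1 A, eps_m = 2, eps_s = 80 this
    is -80.94 kcal/mol.
    """
    if r <= 0:
        raise ValueError("Born radius must be positive")
    if eps_m < 1 or eps_s < 1:
        raise ValueError("relative dielectrics must be >= 1")
    return K_E * q * q / (2.0 * r) * (1.0 / eps_s - 1.0 / eps_m)


def relative_error_percent(exact: float, numeric: float) -> float:
    """|(exact - numeric) / exact| * 100."""
    return abs((exact - numeric) / exact) * 100.0


def electrostatic_energy(mol: Molecule, sol_sys: Solution, sol_ref: Solution) -> float:
    """1/2 sum q_i (phi_i,sys - phi_i,ref), kcal/mol.

    Both solutions must come from the identical mesh — the singular
    numerical error at the point charges only cancels in the same-mesh
    difference.
    """
    m1, m2 = sol_sys.mesh, sol_ref.mesh
    same_geometry = m1 is m2 or (
        (m1.vertices is m2.vertices or np.array_equal(m1.vertices, m2.vertices))
        and (m1.tets is m2.tets or np.array_equal(m1.tets, m2.tets))
    )
    if not same_geometry:  # region labels may differ; the geometry must not
        raise ValueError("solvated and reference solutions must share one mesh")
    return 0.5 * float(np.dot(mol.charges, sol_sys.phi_atoms - sol_ref.phi_atoms))


def electrostatic_solvation(mesh, mol, params, charge_method: str = "direct",
                            bc_mode: str = "dirichlet", pmap=None, cfg=None,
                            membrane_on: bool = True):
    """Two-state solve on one mesh; returns (dG_ele, sol_sys, sol_ref).

    ``charge_method`` is one of ``direct | vertex | average | weighted``.
    The reference state is always linear (uniform eps_m, no ions); the
    solvated state goes through Newton when salt is present.
    """
    load = CHARGE_METHODS[charge_method](mol, mesh)
    sol_sys = solve_state(mesh, mol, load, params, State.SOLVATED,
                          bc_mode=bc_mode, pmap=pmap, cfg=cfg, membrane_on=membrane_on)
    sol_ref = solve_state(mesh, mol, load, params, State.REFERENCE,
                          bc_mode=bc_mode, pmap=pmap, cfg=cfg, membrane_on=membrane_on)
    return electrostatic_energy(mol, sol_sys, sol_ref), sol_sys, sol_ref


@dataclass(frozen=True)
class SurfaceTensionProfile:
    """Depth-dependent surface-tension scaling S(z) for the non-polar term.

    S = 1 in bulk water, ``s_core`` between z1 and z2, with linear ramps of
    width ``w`` outside the slab faces.  ``gamma`` is the surface tension
    in kcal/mol/A^2.
    """

    z1: float
    z2: float
    gamma: float = 0.005
    s_core: float = 0.0
    w: float = 3.0

    def S(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        breaks = [self.z1 - self.w, self.z1, self.z2, self.z2 + self.w]
        vals = [1.0, self.s_core, self.s_core, 1.0]
        return np.interp(z, breaks, vals)


@dataclass
class EnergyReport:
    """Total solvation energy and its parts; dG_sol = dG_ele + dG_np."""

    dG_ele: float
    dG_np: float
    per_atom_dphi: np.ndarray | None = None

    @property
    def dG_sol(self) -> float:
        return self.dG_ele + self.dG_np


def nonpolar_energy(mol: Molecule, sasa: np.ndarray, profile: SurfaceTensionProfile) -> float:
    """gamma * sum_i S(z_i) SA_i, kcal/mol."""
    sasa = np.asarray(sasa, dtype=np.float64)
    if len(sasa) != len(mol):
        raise ValueError("SASA array length does not match the molecule")
    return profile.gamma * float((profile.S(mol.positions[:, 2]) * sasa).sum())


def tilt_scan(mol: Molecule, mesh_builder, angles, energy_fn,
              profile: SurfaceTensionProfile, axis=(0.0, 1.0, 0.0),
              probe: float = 1.4, n_points: int = 960):
    """Total solvation energy vs. rigid tilt angle; returns (curve, argmin).

    For each angle the molecule is rotated about ``axis`` through its
    centroid, ``mesh_builder(rotated)`` produces a labelled mesh, and
    ``energy_fn(mesh, rotated)`` returns the electrostatic energy from the
    two-state solve.  The curve is a list of ``(angle, EnergyReport)``; the
    estimated tilt is the angle of lowest total energy.
    """
    curve = []
    for angle in angles:
        rotated = rotate_molecule(mol, angle, axis)
        mesh = mesh_builder(rotated)
        dg_ele = energy_fn(mesh, rotated)
        sasa = compute_sasa(rotated, probe=probe, n_points=n_points)
        dg_np = nonpolar_energy(rotated, sasa, profile)
        curve.append((float(angle), EnergyReport(dG_ele=dg_ele, dG_np=dg_np)))
    best = min(curve, key=lambda t: t[1].dG_sol)[0]
    return curve, best
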