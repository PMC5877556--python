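"""PQR molecule parsing and solvent-accessible surface areas.

Atoms carry position (Angstrom), partial charge (elementary charges) and
radius (Angstrom).  SASA is computed with the Shrake–Rupley point-sampling
scheme on a Fibonacci sphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Atom", "Molecule", "PQRFormatError", "read_pqr", "write_pqr", "compute_sasa"]


class PQRFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    position: np.ndarray  # (3,) Angstrom
    charge: float  # elementary charges
    radius: float  # Angstrom


@dataclass
class Molecule:
    """Ordered collection of atoms (positions, charges, radii as arrays)."""

    positions: np.ndarray  # (n, 3)
    charges: np.ndarray  # (n,)
    radii: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=np.float64))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=np.float64))
        if not (len(self.positions) == len(self.charges) == len(self.radii)):
            raise ValueError("positions, charges and radii must have equal length")
        if (self.radii <= 0).any():
            raise ValueError("atom radii must be positive")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite atom position")

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def atoms(self) -> list[Atom]:
        return [Atom(p, float(q), float(r)) for p, q, r in zip(self.positions, self.charges, self.radii)]

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def translated(self, shift) -> "Molecule":
        return Molecule(self.positions + np.asarray(shift, dtype=np.float64), self.charges.copy(), self.radii.copy())


def read_pqr(path) -> Molecule:
    """Parse a whitespace-delimited (APBS dialect) PQR file.

    Only ATOM/HETATM records are read; x, y, z, charge, radius are taken as
    the last five numeric fields, which tolerates both chain-ID and
    no-chain-ID dialects.  TER/REMARK/END lines are ignored.
    """
    pos, q, r = [], [], []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = raw.split()
        if not rec or rec[0] not in ("ATOM", "HETATM"):
            continue
        try:
            vals = [float(x) for x in rec[-5:]]
        except ValueError as exc:
            raise PQRFormatError(f"{path}:{ln}: non-numeric coordinate/charge/radius field") from exc
        if len(vals) < 5:
            raise PQRFormatError(f"{path}:{ln}: fewer than five numeric fields")
        pos.append(vals[0:3])
        q.append(vals[3])
        r.append(vals[4])
    if not pos:
        raise PQRFormatError(f"{path}: no ATOM/HETATM records")
    return Molecule(np.array(pos), np.array(q), np.array(r))


def write_pqr(mol: Molecule, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, (p, q, r) in enumerate(zip(mol.positions, mol.charges, mol.radii), start=1):
            fh.write(
                f"ATOM  {i:5d}  C   UNK A{min(i, 9999):4d}    "
                f"{p[0]:10.5f}{p[1]:10.5f}{p[2]:10.5f} {q:11.7f} {r:8.4f}\n"
            )
        fh.write("TER\nEND\n")
    return path


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sasa(mol: Molecule, probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake–Rupley), in A^2.

    For each atom, ``n_points`` quasi-uniform points on the expanded sphere
    of radius ``r_i + probe`` are tested against all neighbouring expanded
    spheres; the accessible fraction times ``4*pi*(r_i+probe)**2`` is the
    atom's SASA.
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 32:
        raise ValueError("n_points must be at least 32")
    n = len(mol)
    sphere = _fibonacci_sphere(n_points)
    expanded = mol.radii + probe
    tree = cKDTree(mol.positions)
    areas = np.empty(n)
    rmax = expanded.max()
    for i in range(n):
        ri = expanded[i]
        pts = mol.positions[i] + ri * sphere
        nbrs = [j for j in tree.query_ball_point(mol.positions[i], ri + rmax) if j != i]
        free = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d = np.linalg.norm(pts - mol.positions[j], axis=1)
            free &= d >= expanded[j]
        areas[i] = 4.0 * np.pi * ri * ri * free.mean()
    return areas
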