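"""Shrake-Rupley solvent-accessible surface area."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Angstrom^2
    probe: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 240,
) -> SasaResult:
    """Per-atom SASA by Shrake-Rupley quadrature.

    For each atom, the fraction of ``n_points`` unit-sphere points at radius
    (r_atom + probe) not inside any neighbor's expanded sphere, times the
    full expanded-sphere area.
    """
    if n_points < 96:
        raise ValueError("n_points must be >= 96 for a usable quadrature")
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    expanded = radii + probe
    unit = sphere_points(n_points)
    areas = np.empty(n)
    d = cdist(coords, coords) if n > 1 else np.zeros((1, 1))
    for i in range(n):
        ri = expanded[i]
        neighbors = np.nonzero((d[i] < ri + expanded) & (np.arange(n) != i))[0]
        pts = coords[i] + ri * unit
        if len(neighbors):
            sep = cdist(pts, coords[neighbors])
            buried = (sep < expanded[neighbors]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ri * ri
    return SasaResult(per_atom=areas, probe=probe, n_sphere_points=n_points)


def sasa(structure, probe: float = 1.4, n_points: int = 240) -> SasaResult:
    """SASA of a parameterized structure's heavy atoms."""
    idx = structure.select(heavy_only=True)
    atoms = list(structure.atoms())
    coords = np.array([atoms[i].coords for i in idx]).reshape(-1, 3)
    radii_list = [atoms[i].solv_radius for i in idx]
    if any(r is None for r in radii_list):
        raise ValueError("structure has atoms without assigned solvation radii")
    radii = np.array(radii_list, dtype=float)
    return sasa_areas(coords, radii, probe=probe, n_points=n_points)
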