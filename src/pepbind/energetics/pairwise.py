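"""Gas-phase pairwise interaction terms (no distance cutoff)."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

COULOMB_CONSTANT = 332.0637  # kcal*mol^-1*Angstrom*e^-2
_SINGULARITY = 1e-6


class SingularityError(ValueError):
    """A cross pair is (near-)coincident."""


def _distances(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    r = cdist(np.atleast_2d(coords_a), np.atleast_2d(coords_b))
    if r.size and float(r.min()) < _SINGULARITY:
        i, j = np.unravel_index(int(r.argmin()), r.shape)
        raise SingularityError(f"atoms {i} and {j} coincide (r={r[i, j]:.2e} A)")
    return r


def coulomb_matrix(
    coords_a: np.ndarray,
    charges_a: np.ndarray,
    coords_b: np.ndarray,
    charges_b: np.ndarray,
    eps: float = 1.0,
    k: float = COULOMB_CONSTANT,
) -> np.ndarray:
    """Per-pair Coulomb energies k*qi*qj/(eps*rij), shape (nA, nB)."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.zeros((len(coords_a), len(coords_b)))
    r = _distances(coords_a, coords_b)
    return k * np.outer(charges_a, charges_b) / (eps * r)


def coulomb_energy(
    coords_a: np.ndarray,
    charges_a: np.ndarray,
    coords_b: np.ndarray,
    charges_b: np.ndarray,
    eps: float = 1.0,
    k: float = COULOMB_CONSTANT,
) -> float:
    """Total cross-pair Coulomb energy between two disjoint atom sets."""
    return float(coulomb_matrix(coords_a, charges_a, coords_b, charges_b, eps, k).sum())


def lj_matrix(
    coords_a: np.ndarray,
    rmin_half_a: np.ndarray,
    eps_a: np.ndarray,
    coords_b: np.ndarray,
    rmin_half_b: np.ndarray,
    eps_b: np.ndarray,
) -> np.ndarray:
    """Per-pair 12-6 energies with Lorentz-Berthelot-style combination.

    rmin_ij = rmin_half_i + rmin_half_j (arithmetic), eps_ij geometric.
    Minimum of the pair potential is -eps_ij at r = rmin_ij.
    """
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.zeros((len(coords_a), len(coords_b)))
    r = _distances(coords_a, coords_b)
    rmin = np.add.outer(np.asarray(rmin_half_a, float), np.asarray(rmin_half_b, float))
    epsij = np.sqrt(np.outer(eps_a, eps_b))
    s6 = (rmin / r) ** 6
    return epsij * (s6 * s6 - 2.0 * s6)


def lj_energy(
    coords_a: np.ndarray,
    rmin_half_a: np.ndarray,
    eps_a: np.ndarray,
    coords_b: np.ndarray,
    rmin_half_b: np.ndarray,
    eps_b: np.ndarray,
) -> float:
    """Total cross-pair Lennard-Jones energy between two disjoint atom sets."""
    return float(lj_matrix(coords_a, rmin_half_a, eps_a, coords_b, rmin_half_b, eps_b).sum())
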