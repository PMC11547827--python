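"""Synthetic inputs for every pipeline stage.

Toy two-chain complexes with a designed contact gap, Gaussian-noise
coordinate ensembles with controlled per-residue amplitude and shared
(correlated) displacement components, hydrogen-bond occupancy by
construction, and noisy one-site saturation binding curves.  All
generators are bit-reproducible given (spec, seed); seeds are explicit
arguments, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._geometry import build_extended_chain
from .ensemble import Ensemble
from .structures import Atom, Residue, Structure

__all__ = [
    "EnsembleSpec",
    "BindingCurveSpec",
    "make_toy_complex",
    "make_ensemble",
    "make_hbond_ensemble",
    "make_binding_curve",
]


@dataclass
class EnsembleSpec:
    """Gaussian-displacement ensemble recipe.

    ``per_atom_sigma`` is either a scalar (Angstrom, every atom) or a
    mapping res_id -> sigma applied to all atoms of matching residues.
    ``correlated_groups`` lists (atom_indices, shared_sigma) pairs; each
    group receives one shared Gaussian displacement per frame on top of
    the independent per-atom noise.
    """

    n_frames: int
    per_atom_sigma: float | dict[int, float] = 0.0
    correlated_groups: list[tuple[list[int], float]] = field(default_factory=list)
    seed: int = 0
    first_frame_is_reference: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        sigmas = (
            [self.per_atom_sigma]
            if np.isscalar(self.per_atom_sigma)
            else list(self.per_atom_sigma.values())
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("sigmas must be >= 0")


@dataclass
class BindingCurveSpec:
    """One-site saturation curve recipe (concentrations in uM)."""

    kd_true: float
    a_max: float
    concentrations: list[float]
    baseline: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_true <= 0:
            raise ValueError("kd_true must be > 0")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")


# ---------------------------------------------------------------------------
# Toy complex


def make_toy_complex(
    n_res_a: int,
    n_res_b: int,
    gap: float,
    seed: int = 0,
    seq_a: str | None = None,
    seq_b: str | None = None,
    jitter: float = 0.02,
) -> Structure:
    """Two extended chains, antiparallel, closest heavy-atom distance == gap.

    Chain A lies along +x, chain B is rotated 180 degrees about z and
    stacked below in z; the z offset is solved so the minimum cross-chain
    heavy-atom distance equals ``gap`` (well within 0.1 Angstrom).  A tiny
    seeded coordinate jitter keeps distinct seeds distinguishable.
    """
    if n_res_a < 2 or n_res_b < 2:
        raise ValueError("chain lengths must be >= 2")
    if gap <= 0:
        raise ValueError("gap must be > 0")
    seq_a = seq_a or "A" * n_res_a
    seq_b = seq_b or "A" * n_res_b
    if len(seq_a) != n_res_a or len(seq_b) != n_res_b:
        raise ValueError("sequence lengths must match residue counts")

    rng = np.random.default_rng(seed)
    a = build_extended_chain(seq_a, chain_id="A")
    b = build_extended_chain(seq_b, chain_id="B")
    b.chains[0] = ("B", b.chains[0][1])
    for res in b.residues():
        res.chain_id = "B"

    xa = a.coords()
    xb = b.coords()
    xa = xa + rng.normal(0.0, jitter, xa.shape)
    xb = xb + rng.normal(0.0, jitter, xb.shape)

    # antiparallel: rotate chain B 180 degrees about z through its centroid
    cb = xb.mean(axis=0)
    xb_rot = xb.copy()
    xb_rot[:, 0] = 2 * cb[0] - xb[:, 0]
    xb_rot[:, 1] = 2 * cb[1] - xb[:, 1]

    heavy_a = a.select(heavy_only=True)
    heavy_b = b.select(heavy_only=True)
    ha, hb = xa[heavy_a], xb_rot[heavy_b]
    dxy2 = (
        (ha[:, None, 0] - hb[None, :, 0]) ** 2
        + (ha[:, None, 1] - hb[None, :, 1]) ** 2
    )
    dz = ha[:, None, 2] - hb[None, :, 2]

    def min_dist(shift: float) -> float:
        return float(np.sqrt(np.min(dxy2 + (dz + shift) ** 2)))

    lo = float(np.max(-dz))  # all (dz + shift) >= 0 -> monotone increasing
    if min_dist(lo) >= gap:
        shift = lo
    else:
        shift = brentq(lambda s: min_dist(s) - gap, lo, lo + gap + 200.0, xtol=1e-10)
    xb_rot[:, 2] -= shift

    a.set_coords(xa)
    b.set_coords(xb_rot)
    return Structure(chains=a.chains + b.chains, source_tag=f"toy_complex(seed={seed})")


# ---------------------------------------------------------------------------
# Ensembles


def _sigma_array(s: Structure, per_atom_sigma: float | dict[int, float]) -> np.ndarray:
    n = s.n_atoms
    if np.isscalar(per_atom_sigma):
        return np.full(n, float(per_atom_sigma))
    out = np.zeros(n)
    for _cid, res, _atom, i in s.atom_table():
        out[i] = float(per_atom_sigma.get(res.res_id, 0.0))
    return out


def make_ensemble(s: Structure, spec: EnsembleSpec) -> Ensemble:
    """Reference + independent Gaussian noise + shared group displacements."""
    rng = np.random.default_rng(spec.seed)
    ref = s.coords()
    n_atoms = ref.shape[0]
    sigma = _sigma_array(s, spec.per_atom_sigma)
    frames = np.empty((spec.n_frames, n_atoms, 3))
    for k in range(spec.n_frames):
        if k == 0 and spec.first_frame_is_reference:
            frames[k] = ref
            # burn the same number of draws to keep later frames seed-stable
            rng.normal(size=(n_atoms, 3))
            for _idx, _gs in spec.correlated_groups:
                rng.normal(size=3)
            continue
        disp = rng.normal(size=(n_atoms, 3)) * sigma[:, None]
        for idx, group_sigma in spec.correlated_groups:
            shared = rng.normal(size=3) * group_sigma
            disp[np.asarray(idx, dtype=int)] += shared
        frames[k] = ref + disp
    return Ensemble(topology=s, frames=frames)


def make_hbond_ensemble(
    occupancy_true: float,
    n_frames: int,
    seed: int = 0,
) -> Ensemble:
    """Two-residue system whose donor/acceptor pair is hydrogen-bonded in
    exactly ``round(occupancy_true * n_frames)`` frames.

    The donor is the backbone N (with an attached H) of chain A residue 1;
    the acceptor is the backbone O of chain B residue 1.  Bonded frames put
    the pair at 2.9 Angstrom with a linear N-H...O arrangement; unbonded
    frames move the acceptor chain 6 Angstrom away.
    """
    if not 0.0 <= occupancy_true <= 1.0:
        raise ValueError("occupancy_true must be a fraction in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    donor_res = Residue(
        chain_id="A",
        res_id=1,
        res_name="ALA",
        atoms=[
            Atom(1, "N", "N", [0.0, 0.0, 0.0]),
            Atom(2, "H", "H", [1.0, 0.0, 0.0]),
            Atom(3, "CA", "C", [-0.8, 1.2, 0.0]),
            Atom(4, "C", "C", [-2.3, 1.1, 0.0]),
            Atom(5, "O", "O", [-2.9, 0.0, 0.0]),
            Atom(6, "CB", "C", [-0.3, 2.0, 1.2]),
        ],
    )
    acceptor_res = Residue(
        chain_id="B",
        res_id=1,
        res_name="ALA",
        atoms=[
            Atom(7, "N", "N", [6.3, 1.2, 0.0]),
            Atom(8, "CA", "C", [5.6, 2.4, 0.0]),
            Atom(9, "C", "C", [4.1, 2.2, 0.0]),
            Atom(10, "O", "O", [2.9, 0.0, 0.0]),  # 2.9 A from donor N, on the N-H line
            Atom(11, "CB", "C", [6.1, 3.2, 1.2]),
        ],
    )
    topology = Structure(
        chains=[("A", [donor_res]), ("B", [acceptor_res])],
        source_tag=f"hbond_ensemble(occ={occupancy_true})",
    )
    ref = topology.coords()
    acceptor_idx = topology.select(chains=["B"], include_hetero=True)

    n_bonded = int(round(occupancy_true * n_frames))
    bonded = np.zeros(n_frames, dtype=bool)
    bonded[:n_bonded] = True
    rng = np.random.default_rng(seed)
    rng.shuffle(bonded)

    frames = np.repeat(ref[None, :, :], n_frames, axis=0)
    for k in range(n_frames):
        if not bonded[k]:
            frames[k, acceptor_idx, 0] += 6.0
    return Ensemble(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# Binding curves


def make_binding_curve(spec: BindingCurveSpec) -> pd.DataFrame:
    """Noisy one-site saturation curve: baseline + a_max*c/(kd+c) + noise."""
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.concentrations, dtype=float)
    response = spec.baseline + spec.a_max * c / (spec.kd_true + c)
    if spec.noise_sd > 0:
        response = response + rng.normal(0.0, spec.noise_sd, size=c.shape)
    return pd.DataFrame({"concentration_uM": c, "response": response})
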