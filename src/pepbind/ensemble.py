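"""Trajectory-style analyses over coordinate ensembles.

Superposition is the optimal least-squares rotation (Kabsch, with the
determinant correction against reflections).  RMSD/RMSF default to heavy
atoms; hydrogen bonds use a geometric distance(+angle) criterion scored as
percent occupancy over frames; DCCM is the normalized covariance of atomic
displacement vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structures import Atom, Residue, Structure

__all__ = [
    "Ensemble",
    "AnalysisSeries",
    "HBondRecord",
    "DegenerateSelectionError",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf",
    "interface_residues",
    "hydrogen_bonds",
    "dccm",
]

DEFAULT_TRAILING_FRACTION = 0.25  # trailing-window generalization of "last 50 ns"


class DegenerateSelectionError(ValueError):
    """Fewer than 3 non-collinear atoms selected for superposition."""


@dataclass
class Ensemble:
    """An ordered stack of coordinate frames over one topology."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def frame_structure(self, index: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.frames[index])
        return s


@dataclass
class AnalysisSeries:
    kind: str  # "rmsd" | "rmsf"
    selection: str
    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    trailing_mean: float | None = None


@dataclass
class HBondRecord:
    donor: str
    hydrogen: str | None
    acceptor: str
    occupancy: float  # percent of frames

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 100.0:
            raise ValueError("occupancy must be a percentage in [0, 100]")


# ---------------------------------------------------------------------------
# Superposition


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best matches ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateSelectionError("superposition needs at least 3 atoms")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateSelectionError("selected atoms are (near-)collinear")
    h = mob_c.T @ ref_c
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = reference.mean(axis=0) - rotation @ mobile.mean(axis=0)
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def _resolve_selection(s: Structure, selection: np.ndarray | None) -> np.ndarray:
    if selection is None:
        return s.select(heavy_only=True)
    return np.asarray(selection, dtype=int)


# ---------------------------------------------------------------------------
# RMSD / RMSF


def rmsd_series(
    e: Ensemble,
    reference_index: int = 0,
    selection: np.ndarray | None = None,
    align: bool = True,
    trailing_fraction: float = DEFAULT_TRAILING_FRACTION,
) -> AnalysisSeries:
    """Per-frame RMSD to a reference frame after per-frame superposition.

    The trailing mean over the last ``trailing_fraction`` of frames is
    reported alongside the series.
    """
    sel = _resolve_selection(e.topology, selection)
    ref = e.frames[reference_index][sel]
    values = np.empty(e.n_frames)
    for k in range(e.n_frames):
        mob = e.frames[k][sel]
        if align:
            _, _, values[k] = superpose(mob, ref)
        else:
            values[k] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    n_tail = max(1, int(round(trailing_fraction * e.n_frames)))
    return AnalysisSeries(
        kind="rmsd",
        selection=f"{len(sel)} atoms",
        values=values,
        trailing_mean=float(values[-n_tail:].mean()),
    )


def rmsf(
    e: Ensemble,
    selection: np.ndarray | None = None,
    align: bool = True,
) -> AnalysisSeries:
    """Per-residue RMSF about the ensemble-mean structure.

    Frames are optionally superposed on the selection first; each residue's
    value is the mean of its selected atoms' per-atom fluctuations.
    """
    sel = _resolve_selection(e.topology, selection)
    stack = e.frames[:, sel, :].copy()
    if align and e.n_frames > 1:
        ref = stack[0]
        for k in range(e.n_frames):
            rot, tr, _ = superpose(stack[k], ref)
            stack[k] = apply_transform(stack[k], rot, tr)
    mean = stack.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))

    # aggregate atoms -> residues, preserving residue order of the selection
    table = e.topology.atom_table()
    res_of = {i: res for _cid, res, _atom, i in table}
    order: list[Residue] = []
    groups: dict[int, list[float]] = {}
    for pos, i in enumerate(sel):
        res = res_of[int(i)]
        key = id(res)
        if key not in groups:
            groups[key] = []
            order.append(res)
        groups[key].append(per_atom[pos])
    values = np.array([np.mean(groups[id(r)]) for r in order])
    labels = [r.label for r in order]
    return AnalysisSeries(kind="rmsf", selection=f"{len(sel)} atoms", values=values, labels=labels)


# ---------------------------------------------------------------------------
# Interface


def interface_residues(
    s: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
) -> dict[str, set[int]]:
    """Residues of either chain with any heavy atom within ``cutoff`` (inclusive)
    of any heavy atom of the other chain."""
    out: dict[str, set[int]] = {chain_a: set(), chain_b: set()}

    def heavy(chain_id: str) -> tuple[np.ndarray, list[int]]:
        coords, rids = [], []
        for res in s.chain(chain_id):
            for atom in res.atoms:
                if atom.is_heavy and not atom.is_hetero:
                    coords.append(atom.coords)
                    rids.append(res.res_id)
        return np.array(coords).reshape(-1, 3), rids

    xa, rid_a = heavy(chain_a)
    xb, rid_b = heavy(chain_b)
    if len(xa) == 0 or len(xb) == 0:
        return out
    d = cdist(xa, xb)
    close = d <= cutoff
    for i in np.nonzero(close.any(axis=1))[0]:
        out[chain_a].add(rid_a[i])
    for j in np.nonzero(close.any(axis=0))[0]:
        out[chain_b].add(rid_b[j])
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds

_POLAR_ELEMENTS = ("N", "O")
_DH_COVALENT = 1.25  # Angstrom, D-H covalent attachment cutoff


def _polar_sites(s: Structure):
    """Donor and acceptor candidates with flat indices; flags H availability."""
    table = s.atom_table()
    coords = s.coords()
    hydrogens = [(res, atom, i) for _c, res, atom, i in table if atom.element == "H"]
    has_h = bool(hydrogens)
    donors = []
    acceptors = []
    for _cid, res, atom, i in table:
        if atom.element not in _POLAR_ELEMENTS or atom.is_hetero:
            continue
        acceptors.append((res, atom, i))
        if has_h:
            attached = None
            h_idx = -1
            for hres, h, hi in hydrogens:
                if hres is res and np.linalg.norm(coords[hi] - coords[i]) <= _DH_COVALENT:
                    attached, h_idx = h, hi
                    break
            if attached is not None:
                donors.append((res, atom, i, attached, h_idx))
        else:
            donors.append((res, atom, i, None, -1))
    return donors, acceptors, has_h


def hydrogen_bonds(
    e: Ensemble,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 135.0,
) -> list[HBondRecord]:
    """Occupancy of every donor/acceptor pair over the ensemble.

    Criterion per frame: donor-acceptor distance <= ``dist_cutoff`` and, when
    a hydrogen is attached to the donor, D-H...A angle >= ``angle_cutoff``
    degrees (distance-only otherwise).  Sorted by occupancy, descending.
    """
    donors, acceptors, _has_h = _polar_sites(e.topology)
    records = []
    for dres, datom, di, hatom, hi in donors:
        for ares, aatom, ai in acceptors:
            if ares is dres:
                continue
            dvec = e.frames[:, ai, :] - e.frames[:, di, :]
            dist = np.linalg.norm(dvec, axis=1)
            ok = dist <= dist_cutoff
            if hatom is not None:
                hv1 = e.frames[:, di, :] - e.frames[:, hi, :]
                hv2 = e.frames[:, ai, :] - e.frames[:, hi, :]
                cosang = np.sum(hv1 * hv2, axis=1) / (
                    np.linalg.norm(hv1, axis=1) * np.linalg.norm(hv2, axis=1) + 1e-12
                )
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                ok = ok & (angle >= angle_cutoff)
            occ = 100.0 * float(np.count_nonzero(ok)) / e.n_frames
            if occ > 0.0:
                records.append(
                    HBondRecord(
                        donor=f"{dres.label}/{datom.name}",
                        hydrogen=f"{dres.label}/{hatom.name}" if hatom is not None else None,
                        acceptor=f"{ares.label}/{aatom.name}",
                        occupancy=occ,
                    )
                )
    records.sort(key=lambda r: (-r.occupancy, r.donor, r.acceptor))
    return records


# ---------------------------------------------------------------------------
# DCCM


def dccm(e: Ensemble, selection: np.ndarray | None = None) -> np.ndarray:
    """Normalized displacement covariance matrix, entries in [-1, 1]."""
    sel = _resolve_selection(e.topology, selection)
    x = e.frames[:, sel, :]
    disp = x - x.mean(axis=0)
    cov = np.einsum("fik,fjk->ij", disp, disp) / e.n_frames
    var = np.diag(cov).copy()
    var[var <= 0] = np.inf  # static atoms correlate with nothing
    norm = np.sqrt(np.outer(var, var))
    c = cov / norm
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)
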