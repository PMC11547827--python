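"""Idealized peptide geometry templates (internal).

Crude but deterministic coordinates: an extended zig-zag backbone with
plausible bond lengths, and side chains grown atom-by-atom along the
CA->CB direction from a per-residue connectivity tree.  Good enough for
charge bookkeeping, clash relief and rank-ordering toys — not for real
structural work.
"""

from __future__ import annotations

import numpy as np

from .structures import Atom, ONE_TO_THREE, Residue, Structure

# Children beyond CB: (atom_name, parent_name), in placement order.
SIDECHAIN_TREE: dict[str, list[tuple[str, str]]] = {
    "ALA": [],
    "ARG": [("CG", "CB"), ("CD", "CG"), ("NE", "CD"), ("CZ", "NE"),
            ("NH1", "CZ"), ("NH2", "CZ")],
    "ASN": [("CG", "CB"), ("OD1", "CG"), ("ND2", "CG")],
    "ASP": [("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")],
    "CYS": [("SG", "CB")],
    "GLN": [("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("NE2", "CD")],
    "GLU": [("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("OE2", "CD")],
    "GLY": [],
    "HIS": [("CG", "CB"), ("ND1", "CG"), ("CD2", "CG"), ("CE1", "ND1"),
            ("NE2", "CD2")],
    "ILE": [("CG1", "CB"), ("CG2", "CB"), ("CD1", "CG1")],
    "LEU": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")],
    "LYS": [("CG", "CB"), ("CD", "CG"), ("CE", "CD"), ("NZ", "CE")],
    "MET": [("CG", "CB"), ("SD", "CG"), ("CE", "SD")],
    "PHE": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("CE1", "CD1"),
            ("CE2", "CD2"), ("CZ", "CE1")],
    "PRO": [("CG", "CB"), ("CD", "CG")],
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB"), ("CG2", "CB")],
    "TRP": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("NE1", "CD1"),
            ("CE2", "CD2"), ("CE3", "CD2"), ("CZ2", "CE2"), ("CZ3", "CE3"),
            ("CH2", "CZ2")],
    "TYR": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("CE1", "CD1"),
            ("CE2", "CD2"), ("CZ", "CE1"), ("OH", "CZ")],
    "VAL": [("CG1", "CB"), ("CG2", "CB")],
}

ALANINE_HEAVY_ATOMS = ("N", "CA", "C", "O", "CB")

_RESIDUE_PITCH = 3.8  # Angstrom per residue along the chain axis
_BOND = {"S": 1.81}
_DEFAULT_BOND = 1.50


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def _normalize(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("degenerate direction vector")
    return v / n


def cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray, length: float = 1.53) -> np.ndarray:
    """Place CB roughly tetrahedrally off the N-CA-C plane."""
    u1 = _normalize(n - ca)
    u2 = _normalize(c - ca)
    bisector = _normalize(u1 + u2)
    normal = _normalize(np.cross(u1, u2))
    return ca + length * _normalize(-0.577 * bisector + 0.817 * normal)


def grow_sidechain(
    res_name: str,
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    cb: np.ndarray | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Side-chain heavy atoms (CB onward) for one residue, idealized.

    ``cb`` overrides the ideal CB placement (used to keep the wild-type
    CA->CB direction when mutating in place).
    """
    if res_name == "GLY":
        return []
    if cb is None:
        cb = cb_position(n, ca, c)
    placed: dict[str, np.ndarray] = {"N": n, "CA": ca, "C": c, "CB": cb}
    parent_of: dict[str, str] = {"CB": "CA", "CA": "N"}
    out: list[tuple[str, np.ndarray]] = [("CB", cb)]
    child_rank: dict[str, int] = {}
    for name, parent in SIDECHAIN_TREE.get(res_name, []):
        grand = parent_of[parent]
        ext = _normalize(placed[parent] - placed[grand])
        # deterministic perpendicular for branch separation
        trial = np.array([1.0, 0.0, 0.0])
        if abs(float(np.dot(trial, ext))) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        perp = _normalize(np.cross(ext, trial))
        rank = child_rank.get(parent, 0)
        child_rank[parent] = rank + 1
        spread = (0.0, 0.9, -0.9, 0.45)[rank % 4]
        bond = _BOND.get(name[0], _DEFAULT_BOND)
        pos = placed[parent] + bond * _normalize(ext + spread * perp)
        placed[name] = pos
        parent_of[name] = parent
        out.append((name, pos))
    return out


def backbone_positions(index: int) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O of residue ``index`` (0-based) on an extended zig-zag."""
    x0 = _RESIDUE_PITCH * index
    flip = 1.0 if index % 2 == 0 else -1.0
    return {
        "N": np.array([x0 + 0.00, 0.00, 0.0]),
        "CA": np.array([x0 + 1.23, 0.80 * flip, 0.0]),
        "C": np.array([x0 + 2.45, 0.00, 0.0]),
        "O": np.array([x0 + 2.77, -1.18 * flip, 0.0]),
    }


def make_residue(
    res_name: str,
    chain_id: str,
    res_id: int,
    backbone: dict[str, np.ndarray],
    serial_start: int = 1,
) -> Residue:
    atoms = []
    serial = serial_start
    for name in ("N", "CA", "C", "O"):
        atoms.append(Atom(serial, name, _element_of(name), backbone[name]))
        serial += 1
    for name, pos in grow_sidechain(res_name, backbone["N"], backbone["CA"], backbone["C"]):
        atoms.append(Atom(serial, name, _element_of(name), pos))
        serial += 1
    return Residue(chain_id=chain_id, res_id=res_id, res_name=res_name, atoms=atoms)


def build_extended_chain(sequence: str, chain_id: str = "A") -> Structure:
    """One chain in extended conformation from a one-letter sequence."""
    residues = []
    serial = 1
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE[aa]
        res = make_residue(res_name, chain_id, i + 1, backbone_positions(i), serial)
        serial += len(res.atoms)
        residues.append(res)
    return Structure(chains=[(chain_id, residues)])


def build_ring_chain(sequence: str, chain_id: str = "A") -> Structure:
    """A macrocycle-shaped chain: CA atoms near a circle, frames tangential.

    The ring radius is set from the per-residue pitch so consecutive CA-CA
    distances stay near 3.8 A; the head and tail end up adjacent, leaving
    only a short closure refinement to downstream callers.
    """
    n = len(sequence)
    if n < 3:
        raise ValueError("ring needs at least 3 residues")
    radius = _RESIDUE_PITCH / (2.0 * np.sin(np.pi / n))
    residues = []
    serial = 1
    for i, aa in enumerate(sequence):
        theta = 2.0 * np.pi * i / n
        center = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        flip = 1.0 if i % 2 == 0 else -1.0
        backbone = {
            "N": center - 1.23 * tangent,
            "CA": center + 0.30 * flip * np.array([0.0, 0.0, 1.0]),
            "C": center + 1.22 * tangent,
            "O": center + 1.22 * tangent + 1.22 * radial,
        }
        res_name = ONE_TO_THREE[aa]
        res = make_residue(res_name, chain_id, i + 1, backbone, serial)
        serial += len(res.atoms)
        residues.append(res)
    return Structure(chains=[(chain_id, residues)])
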