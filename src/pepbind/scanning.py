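"""Computational alanine scanning and virtual point mutation.

Alanine scanning is single-trajectory: mutant coordinates are obtained by
truncating the side chain beyond CB on the existing frames (no
re-sampling), the binding energy is recomputed, and the reported change is
ddg = dg_wild - dg_mut, so a wild-type residue that stabilizes binding
gives ddg < 0.  A residue is a hot spot when ddg <= -threshold (default
2 kcal/mol); the direction convention is a parameter.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import ALANINE_HEAVY_ATOMS, grow_sidechain
from .energetics import PBSettings, binding_energy
from .ensemble import Ensemble
from .forcefield import ParamTable
from .structures import Atom, ONE_TO_THREE, Structure, THREE_TO_ONE

__all__ = [
    "AlanineScanEntry",
    "MutationSpec",
    "MutationResult",
    "SelectionError",
    "parse_mutation",
    "mutate_to_alanine",
    "alanine_scan",
    "classify_hotspots",
    "point_mutation",
]

HOTSPOT_THRESHOLD = 2.0  # kcal/mol
_BACKBONE_KEEP = {"N", "CA", "C", "O", "OXT", "CB", "H", "H1", "H2", "H3", "HA"}
_CLASH_FLOOR = 1.5  # Angstrom
_RELIEF_TARGET = 2.5  # soft-repulsion onset distance


class SelectionError(ValueError):
    """Residue not inside the receptor/ligand selection."""


@dataclass
class AlanineScanEntry:
    chain_id: str
    res_id: int
    res_name: str
    dg_wild: float
    dg_mut: float
    is_hotspot: bool = False
    skipped: bool = False
    flagged: bool = False  # e.g. proline backbone caveat

    @property
    def ddg(self) -> float:
        return self.dg_wild - self.dg_mut


@dataclass
class MutationSpec:
    chain_id: str
    res_id: int
    from_aa: str
    to_aa: str

    @property
    def label(self) -> str:
        return f"{self.from_aa}{self.res_id}{self.to_aa}"


@dataclass
class MutationResult:
    structure: Structure
    spec: MutationSpec
    clash_warning: bool = False


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation(label: str, chain_id: str = "A") -> MutationSpec:
    """Parse a label like ``L16R`` into a MutationSpec."""
    m = _MUTATION_RE.match(label.strip().upper())
    if not m or m.group(1) not in ONE_TO_THREE or m.group(3) not in ONE_TO_THREE:
        raise ValueError(f"cannot parse mutation label {label!r} (expected e.g. L16R)")
    return MutationSpec(chain_id=chain_id, res_id=int(m.group(2)),
                        from_aa=m.group(1), to_aa=m.group(3))


# ---------------------------------------------------------------------------
# alanine truncation


def mutate_to_alanine(s: Structure, chain_id: str, res_id: int) -> Structure:
    """Truncate the side chain beyond CB and rename the residue ALA.

    Glycine is returned unchanged with a warning (no side chain to cut);
    alanine is a fixed point.
    """
    out = s.copy()
    for res in out.chain(chain_id):
        if res.res_id != res_id:
            continue
        if res.res_name == "GLY":
            warnings.warn(f"{res.label}: glycine has no side chain; skipping")
            return out
        res.atoms = [a for a in res.atoms if a.name in _BACKBONE_KEEP]
        res.res_name = "ALA"
        for a in res.atoms:
            a.charge = None  # force re-parameterization downstream
        return out
    raise KeyError(f"residue {res_id} not found in chain {chain_id}")


def _kept_atom_indices(s: Structure, chain_id: str, res_id: int) -> np.ndarray:
    keep = []
    for cid, res, atom, i in s.atom_table():
        if cid == chain_id and res.res_id == res_id:
            if atom.name not in _BACKBONE_KEEP:
                continue
        keep.append(i)
    return np.array(keep, dtype=int)


def alanine_scan(
    e: Ensemble,
    receptor_chains,
    ligand_chains,
    residues: list[tuple[str, int]],
    settings: PBSettings | None = None,
    trailing_fraction: float = 1.0,
    table: ParamTable | None = None,
    threshold: float = HOTSPOT_THRESHOLD,
    stabilizing_sign: int = -1,
) -> list[AlanineScanEntry]:
    """Scan the listed (chain, res_id) residues; wild-type scored once.

    Output order matches the input residue order; reruns are bit-identical
    (everything downstream is deterministic).
    """
    settings = settings or PBSettings()
    all_chains = set(receptor_chains) | set(ligand_chains)
    wild = binding_energy(e, receptor_chains, ligand_chains, settings,
                          trailing_fraction, table)
    entries: list[AlanineScanEntry] = []
    for chain_id, res_id in residues:
        if chain_id not in all_chains:
            raise SelectionError(
                f"residue {chain_id}:{res_id} lies outside both partners"
            )
        res = next(r for r in e.topology.chain(chain_id) if r.res_id == res_id)
        if res.res_name == "GLY":
            warnings.warn(f"{res.label}: glycine skipped in alanine scan")
            entries.append(AlanineScanEntry(chain_id, res_id, res.res_name,
                                            wild.g_bind, wild.g_bind, skipped=True))
            continue
        if res.res_name == "ALA":
            entries.append(AlanineScanEntry(chain_id, res_id, res.res_name,
                                            wild.g_bind, wild.g_bind))
            continue
        mut_topo = mutate_to_alanine(e.topology, chain_id, res_id)
        keep = _kept_atom_indices(e.topology, chain_id, res_id)
        mut_ens = Ensemble(topology=mut_topo, frames=e.frames[:, keep, :])
        mut = binding_energy(mut_ens, receptor_chains, ligand_chains, settings,
                             trailing_fraction, table)
        entries.append(AlanineScanEntry(
            chain_id, res_id, res.res_name, wild.g_bind, mut.g_bind,
            flagged=(res.res_name == "PRO"),
        ))
    for entry in entries:
        entry.is_hotspot = (
            not entry.skipped
            and stabilizing_sign * entry.ddg >= threshold
        )
    return entries


def classify_hotspots(
    entries: list[AlanineScanEntry],
    threshold: float = HOTSPOT_THRESHOLD,
    stabilizing_sign: int = -1,
) -> list[AlanineScanEntry]:
    """Entries whose wild-type side chain stabilizes binding by >= threshold.

    With the default convention (ddg = dg_wild - dg_mut) a stabilizing
    residue gives ddg <= -threshold; pass ``stabilizing_sign=+1`` for the
    opposite bookkeeping.
    """
    return [
        en for en in entries
        if not en.skipped and stabilizing_sign * en.ddg >= threshold
    ]


# ---------------------------------------------------------------------------
# point mutation


def point_mutation(s: Structure, spec: MutationSpec) -> MutationResult:
    """Swap one side chain for an idealized template, deterministically.

    The new CB keeps the wild-type CA->CB direction; remaining atoms come
    from the internal template, followed by 50 steepest-descent steps of
    clash relief moving the new atoms only.  If any new heavy atom still
    sits closer than 1.5 Angstrom to the environment, the result carries a
    clash warning flag.
    """
    res = next((r for r in s.chain(spec.chain_id) if r.res_id == spec.res_id), None)
    if res is None:
        raise KeyError(f"residue {spec.res_id} not in chain {spec.chain_id}")
    if THREE_TO_ONE.get(res.res_name) != spec.from_aa:
        raise ValueError(
            f"{spec.label}: structure has {res.res_name} at "
            f"{spec.chain_id}:{spec.res_id}, not {spec.from_aa}"
        )
    out = s.copy()
    res = next(r for r in out.chain(spec.chain_id) if r.res_id == spec.res_id)
    if spec.from_aa == spec.to_aa:
        return MutationResult(structure=out, spec=spec)

    to_res = ONE_TO_THREE[spec.to_aa]
    n = res.atom("N").coords
    ca = res.atom("CA").coords
    c = res.atom("C").coords
    cb_dir = None
    if res.has_atom("CB"):
        wild_cb = res.atom("CB").coords
        cb_dir = wild_cb - ca
        norm = np.linalg.norm(cb_dir)
        cb = ca + 1.53 * cb_dir / norm if norm > 1e-6 else None
    else:
        cb = None

    res.atoms = [a for a in res.atoms if a.name in _BACKBONE_KEEP and a.name != "CB"]
    res.res_name = to_res
    new_atoms: list[Atom] = []
    serial = max((a.serial for a in out.atoms()), default=0) + 1
    for name, pos in grow_sidechain(to_res, n, ca, c, cb=cb):
        new_atoms.append(Atom(serial, name, name[0], pos))
        serial += 1
    res.atoms.extend(new_atoms)
    for a in res.atoms:
        a.charge = None

    clash = _relieve_clashes(out, res, new_atoms)
    return MutationResult(structure=out, spec=spec, clash_warning=clash)


def _relieve_clashes(s: Structure, res, new_atoms: list[Atom],
                     n_steps: int = 50, step: float = 0.05) -> bool:
    """Soft-repulsion steepest descent moving only the new atoms."""
    env = np.array([
        a.coords for r in s.residues() if r is not res
        for a in r.atoms if a.is_heavy
    ]).reshape(-1, 3)
    if len(env) == 0 or not new_atoms:
        return False
    pos = np.array([a.coords for a in new_atoms])

    def energy_grad(p: np.ndarray):
        diff = p[:, None, :] - env[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        overlap = np.maximum(0.0, _RELIEF_TARGET - d)
        e_val = float((overlap ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            coef = np.where(d > 1e-9, -2.0 * overlap / d, 0.0)
        g = (coef[:, :, None] * diff).sum(axis=1)
        return e_val, g

    e_val, g = energy_grad(pos)
    lr = step
    for _ in range(n_steps):
        trial = pos - lr * g
        e_trial, g_trial = energy_grad(trial)
        if e_trial <= e_val:
            pos, e_val, g = trial, e_trial, g_trial
        else:
            lr *= 0.5
        if e_val == 0.0:
            break
    for a, p in zip(new_atoms, pos):
        a.coords = p
    diff = pos[:, None, :] - env[None, :, :]
    min_d = float(np.linalg.norm(diff, axis=2).min())
    return min_d < _CLASH_FLOOR
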