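"""Per-atom parameter assignment from a packaged reduced parameter table.

The table is deliberately small: charges to two decimals on heavy atoms,
one Lennard-Jones class per element, Bondi-like solvation radii.  It is not
a force field — it only has to make the energetics modules self-contained
and keep every residue at its integer formal charge.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import yaml

from .structures import Atom, Residue, Structure

__all__ = [
    "AtomParams",
    "ParamTable",
    "ParameterizationError",
    "load_param_table",
    "assign_parameters",
]

DEFAULT_TABLE_RESOURCE = "params_reduced_v1.yaml"


class ParameterizationError(ValueError):
    """An atom could not be resolved against the parameter table."""


@dataclass(frozen=True)
class AtomParams:
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    solv_radius: float

    def __post_init__(self) -> None:
        if self.lj_rmin_half <= 0 or self.solv_radius <= 0 or self.lj_epsilon < 0:
            raise ValueError("invalid Lennard-Jones / radius parameters")


class ParamTable:
    """(res_name, atom_name) -> AtomParams with element-keyed fallbacks."""

    def __init__(self, raw: dict):
        self.version = raw.get("version", 0)
        self._lj = {e: (d["rmin_half"], d["epsilon"]) for e, d in raw["lj_by_element"].items()}
        self._radius = dict(raw["solv_radius_by_element"])
        self._fallback_q = dict(raw.get("fallback_charges", {}))
        self.formal_charges = {k: float(v) for k, v in raw["formal_charges"].items()}
        self._backbone_q = {k: float(v) for k, v in raw["backbone_charges"].items()}
        self._sidechain_q = {
            res: {a: float(q) for a, q in entries.items()}
            for res, entries in raw["sidechain_charges"].items()
        }

    def residue_charges(self, res_name: str) -> dict[str, float]:
        if res_name not in self._sidechain_q:
            raise ParameterizationError(f"no charge entries for residue {res_name!r}")
        merged = dict(self._backbone_q)
        merged.update(self._sidechain_q[res_name])
        return merged

    def lookup(self, res_name: str, atom_name: str, element: str) -> tuple[AtomParams, bool]:
        """Resolve one atom; returns (params, used_fallback)."""
        if element not in self._lj or element not in self._radius:
            raise ParameterizationError(
                f"({res_name}, {atom_name}): element {element!r} has no LJ/radius class"
            )
        rmin_half, epsilon = self._lj[element]
        radius = self._radius[element]
        used_fallback = False
        charges = self._sidechain_q.get(res_name, {})
        if atom_name in self._backbone_q and element != "H":
            charge = self._backbone_q[atom_name]
        elif atom_name in charges:
            charge = charges[atom_name]
        elif element in self._fallback_q:
            charge = self._fallback_q[element]
            used_fallback = True
        else:
            raise ParameterizationError(
                f"({res_name}, {atom_name}): atom not in table and element "
                f"{element!r} has no fallback charge"
            )
        return AtomParams(charge, rmin_half, epsilon, radius), used_fallback


def load_param_table(path: str | None = None) -> ParamTable:
    """Load the packaged reduced table, or a user override from ``path``."""
    if path is None:
        source = resources.files("pepbind.data").joinpath(DEFAULT_TABLE_RESOURCE)
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return ParamTable(raw)


def assign_parameters(
    s: Structure,
    table: ParamTable | None = None,
    in_place: bool = False,
) -> tuple[Structure, list[str]]:
    """Attach charge/LJ/radius parameters to every atom.

    Returns the parameterized structure and a report of fallback uses
    (one ``chain:RESid/atom`` entry per atom resolved by element fallback).
    Deterministic and order-independent: each atom resolves from its own
    (res_name, atom_name, element) triple alone.
    """
    if table is None:
        table = load_param_table()
    out = s if in_place else s.copy()
    report: list[str] = []
    for res in out.residues():
        for atom in res.atoms:
            params, used_fallback = table.lookup(res.res_name, atom.name, atom.element)
            atom.charge = params.charge
            atom.lj_rmin_half = params.lj_rmin_half
            atom.lj_epsilon = params.lj_epsilon
            atom.solv_radius = params.solv_radius
            if used_fallback:
                report.append(f"{res.label}/{atom.name}")
    return out, report


def total_charge(s: Structure) -> float:
    """Sum of assigned atomic charges (requires assign_parameters first)."""
    q = 0.0
    for atom in s.atoms():
        if atom.charge is None:
            raise ParameterizationError(f"atom {atom.name} has no assigned charge")
        q += atom.charge
    return q
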