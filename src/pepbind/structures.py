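"""PDB-backed coordinate model: atoms, residues, chains and fragment surgery.

The coordinate and indexing conventions defined here are shared by every
other module: residues are renumbered 1-based and sequential within each
chain, with the original author numbering (including insertion codes)
retained as a label for reporting.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "EmptyInputError",
    "ChainLookupError",
    "FragmentRangeError",
    "read_pdb",
    "read_ensemble_models",
    "write_pdb",
    "write_ensemble_models",
    "select_chains",
    "extract_fragment",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "STANDARD_RESIDUES",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)


class PDBParseError(ValueError):
    """Malformed PDB coordinate record; message carries the line number."""


class EmptyInputError(ValueError):
    """File contained no coordinate records."""


class ChainLookupError(KeyError):
    """Requested chain id absent; message lists the available ids."""


class FragmentRangeError(ValueError):
    """A residue interval falls outside the chain."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    is_hetero: bool = False
    # Filled in by forcefield.assign_parameters; None until then.
    charge: float | None = None
    lj_rmin_half: float | None = None
    lj_epsilon: float | None = None
    solv_radius: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    chain_id: str
    res_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    author_id: str = ""

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_RESIDUES

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.res_name}{self.res_id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.res_id}"


@dataclass
class Structure:
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    source_tag: str = ""

    # -- basic accessors ---------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise ChainLookupError(
            f"chain {chain_id!r} not found; available: {','.join(self.chain_ids)}"
        )

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        for cid, residues in self.chains:
            if chain_id is None or cid == chain_id:
                yield from residues

    def atoms(self, chain_id: str | None = None) -> Iterator[Atom]:
        for res in self.residues(chain_id):
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords(self) -> np.ndarray:
        """All atom coordinates in file order, shape (n_atoms, 3)."""
        arr = [a.coords for a in self.atoms()]
        return np.array(arr, dtype=float).reshape(-1, 3)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = list(self.atoms())
        if coords.shape != (len(atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} incongruent with "
                f"{len(atoms)} atoms"
            )
        for atom, xyz in zip(atoms, coords):
            atom.coords = xyz.copy()

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain(chain_id))

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    # -- selections --------------------------------------------------------
    def atom_table(self) -> list[tuple[str, Residue, Atom, int]]:
        """Flat (chain_id, residue, atom, flat_index) rows in file order."""
        rows = []
        i = 0
        for cid, residues in self.chains:
            for res in residues:
                for atom in res.atoms:
                    rows.append((cid, res, atom, i))
                    i += 1
        return rows

    def select(
        self,
        chains: Iterable[str] | None = None,
        heavy_only: bool = False,
        atom_names: Iterable[str] | None = None,
        residue_ids: Iterable[tuple[str, int]] | None = None,
        include_hetero: bool = False,
    ) -> np.ndarray:
        """Flat atom indices matching all given filters (AND semantics)."""
        chain_set = set(chains) if chains is not None else None
        name_set = set(atom_names) if atom_names is not None else None
        rid_set = set(residue_ids) if residue_ids is not None else None
        out = []
        for cid, res, atom, i in self.atom_table():
            if chain_set is not None and cid not in chain_set:
                continue
            if heavy_only and not atom.is_heavy:
                continue
            if name_set is not None and atom.name not in name_set:
                continue
            if rid_set is not None and (cid, res.res_id) not in rid_set:
                continue
            if atom.is_hetero and not include_hetero:
                continue
            out.append(i)
        return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# PDB parsing


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] in "Hh" or atom_name.strip()[0].isdigit():
        return "H"
    two = stripped[:2].upper()
    # Only elements plausibly in protein PDB files.
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA") and len(atom_name.strip()) <= 2:
        return two.capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, int, str, str, Atom]:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    name = line[12:16].strip()
    altloc = line[16:17]
    res_name = line[17:20].strip()
    chain_id = line[21:22].strip() or "A"
    try:
        auth_seq = line[22:26].strip()
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate field: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    element = element.capitalize() if len(element) > 1 else element.upper()
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        coords=np.array([x, y, z]),
        is_hetero=line.startswith("HETATM"),
    )
    return chain_id, res_name, serial, auth_seq + icode, altloc, atom


def _parse_model_lines(lines: list[tuple[int, str]], source_tag: str) -> Structure:
    struct = Structure(source_tag=source_tag)
    chain_map: dict[str, list[Residue]] = {}
    current_key: tuple[str, str, str] | None = None
    current_res: Residue | None = None
    for lineno, line in lines:
        chain_id, res_name, _serial, author_id, altloc, atom = _parse_atom_line(line, lineno)
        if altloc not in ("", " ", "A"):
            continue  # deterministic single-conformer model: altloc A or blank
        key = (chain_id, author_id, res_name)
        if key != current_key:
            if chain_id not in chain_map:
                chain_map[chain_id] = []
                struct.chains.append((chain_id, chain_map[chain_id]))
            residues = chain_map[chain_id]
            current_res = Residue(
                chain_id=chain_id,
                res_id=len(residues) + 1,
                res_name=res_name,
                author_id=author_id,
            )
            residues.append(current_res)
            current_key = key
        assert current_res is not None
        current_res.atoms.append(atom)
    return struct


def _split_models(path: str) -> list[list[tuple[int, str]]]:
    models: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    in_model = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("MODEL"):
                if current:
                    models.append(current)
                    current = []
                in_model = True
            elif line.startswith("ENDMDL"):
                models.append(current)
                current = []
                in_model = False
            elif line.startswith(("ATOM  ", "HETATM", "ATOM\t")) or (
                line.startswith("ATOM") and len(line) > 54
            ):
                current.append((lineno, line))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    return models


def read_pdb(path: str) -> Structure:
    """Parse a PDB file into a :class:`Structure` (first MODEL only).

    Insertion codes are collapsed into the sequential 1-based ``res_id``;
    the author numbering string is kept on ``Residue.author_id``.
    """
    models = _split_models(path)
    return _parse_model_lines(models[0], source_tag=str(path))


def read_ensemble_models(path: str) -> tuple[Structure, np.ndarray]:
    """Parse a multi-MODEL PDB; returns (topology, frames[n_frames, n_atoms, 3])."""
    models = _split_models(path)
    topology = _parse_model_lines(models[0], source_tag=str(path))
    n_atoms = topology.n_atoms
    frames = np.empty((len(models), n_atoms, 3), dtype=float)
    for k, model_lines in enumerate(models):
        struct = topology if k == 0 else _parse_model_lines(model_lines, source_tag=str(path))
        if struct.n_atoms != n_atoms:
            raise PDBParseError(
                f"MODEL {k + 1} has {struct.n_atoms} atoms, expected {n_atoms}"
            )
        frames[k] = struct.coords()
    return topology, frames


def _format_atom_line(atom: Atom, res: Residue, chain_id: str, serial: int) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"{record}{serial:>5d} {name:<4s} {res.res_name:<3s} {chain_id:>1s}"
        f"{res.res_id:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def _structure_lines(s: Structure, serial_start: int = 1) -> list[str]:
    lines = []
    serial = serial_start
    for cid, residues in s.chains:
        for res in residues:
            for atom in res.atoms:
                lines.append(_format_atom_line(atom, res, cid, serial))
                serial += 1
        lines.append("TER")
    return lines


def write_pdb(s: Structure, path: str) -> None:
    """Write standard ATOM records, 3-decimal coordinates, TER between chains."""
    lines = _structure_lines(s)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\nEND\n")


def write_ensemble_models(topology: Structure, frames: np.ndarray, path: str) -> None:
    """Write an ensemble as a multi-MODEL PDB over a fixed topology."""
    frames = np.asarray(frames, dtype=float)
    work = topology.copy()
    with open(path, "w") as fh:
        for k, frame in enumerate(frames, start=1):
            work.set_coords(frame)
            fh.write(f"MODEL     {k:>4d}\n")
            fh.write("\n".join(_structure_lines(work)) + "\nENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Chain / fragment operations


def select_chains(s: Structure, ids: Iterable[str]) -> Structure:
    """Return a structure holding exactly the named chains, order preserved."""
    wanted = set(ids)
    missing = wanted - set(s.chain_ids)
    if missing:
        raise ChainLookupError(
            f"chain(s) {','.join(sorted(missing))} not found; "
            f"available: {','.join(s.chain_ids)}"
        )
    out = Structure(source_tag=s.source_tag)
    for cid, residues in s.chains:
        if cid in wanted:
            out.chains.append((cid, _copy.deepcopy(residues)))
    return out


def extract_fragment(
    s: Structure,
    chain: str,
    ranges: Sequence[tuple[int, int]],
    new_chain_id: str = "A",
) -> tuple[Structure, str]:
    """Splice residue intervals (inclusive, by sequential res_id) into one chain.

    Residues are concatenated in the listed interval order and renumbered
    from 1; the one-letter sequence of the new chain is returned alongside.
    """
    residues = s.chain(chain)
    by_id = {r.res_id: r for r in residues}
    picked: list[Residue] = []
    for start, end in ranges:
        if start > end:
            raise FragmentRangeError(f"empty interval {start}-{end}")
        for rid in range(start, end + 1):
            if rid not in by_id:
                raise FragmentRangeError(
                    f"residue {rid} outside chain {chain} (1-{len(residues)})"
                )
            picked.append(by_id[rid])
    new_residues = []
    for i, res in enumerate(picked, start=1):
        r = _copy.deepcopy(res)
        r.res_id = i
        r.chain_id = new_chain_id
        new_residues.append(r)
    frag = Structure(chains=[(new_chain_id, new_residues)], source_tag=s.source_tag)
    return frag, "".join(r.one_letter for r in new_residues)
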