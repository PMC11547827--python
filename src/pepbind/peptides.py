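"""Cyclic peptide design layer: truncation, cyclization, naming, geometry.

Two head-to-tail strategies: ``GP`` appends Gly then Pro and closes a
backbone amide to the N-terminus; ``CC`` prepends and appends a Cys and
closes a disulfide between residues 1 and N.  Designs are named
``{R1|α}_{GP|CC}{serial}``; the alpha source also accepts the spelled-out
``alpha`` form in parsing and file names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._geometry import build_ring_chain
from .structures import Structure

__all__ = [
    "LinearCandidate",
    "CyclicPeptideDesign",
    "BuildResult",
    "NonClosureError",
    "load_design_table",
    "load_linear_candidates",
    "propose_truncations",
    "cyclize",
    "name_design",
    "parse_design_name",
    "enumerate_designs",
    "build_cyclic_geometry",
]

STRATEGIES = ("GP", "CC")
SOURCES = ("R1", "α")

AMIDE_CN_TARGET = 1.33  # Angstrom
DISULFIDE_SS_TARGET = 2.05


class NonClosureError(RuntimeError):
    """Ring closure residual exceeded tolerance after relaxation."""


@dataclass
class LinearCandidate:
    sequence: str
    source: str  # "R1" | "α"
    serial: int
    region: str = ""
    ranges: list[tuple[int, int]] = field(default_factory=list)
    key_covered: int = 0

    def __post_init__(self) -> None:
        if self.serial < 0:
            raise ValueError("serial must be >= 0")
        if self.ranges:
            total = sum(end - start + 1 for start, end in self.ranges)
            if total != len(self.sequence):
                raise ValueError("sequence length must equal total interval length")


@dataclass
class CyclicPeptideDesign:
    base: LinearCandidate
    strategy: str  # "GP" | "CC"
    sequence: str
    closure: str  # e.g. "amide(C9-N1)" or "disulfide(SG1-SG19)"
    external_control: bool = False

    @property
    def name(self) -> str:
        return name_design(self)


@dataclass
class BuildResult:
    structure: Structure
    closure_atoms: tuple[str, str]
    closure_distance: float
    closure_target: float
    residual_history: list[float]


# ---------------------------------------------------------------------------
# fixtures


def load_design_table() -> pd.DataFrame:
    """The packaged linear design sequences (plus literature controls)."""
    src = resources.files("pepbind.data").joinpath("design_sequences.csv")
    with src.open() as fh:
        return pd.read_csv(fh)


def load_linear_candidates(include_controls: bool = False) -> list[LinearCandidate]:
    table = load_design_table()
    out = []
    for row in table.itertuples():
        if row.role != "design" and not include_controls:
            continue
        source = "α" if row.source == "alpha" else row.source
        out.append(LinearCandidate(sequence=row.sequence, source=source,
                                   serial=int(row.serial), region=row.region))
    return out


# ---------------------------------------------------------------------------
# truncation


def propose_truncations(
    s: Structure,
    chain_id: str,
    key_residues: set[int],
    window_lengths: range,
) -> list[LinearCandidate]:
    """Contiguous windows over the chain ranked by key-residue coverage.

    Ranking: more keys covered first, then shorter window, then lower
    start.  Non-contiguous splices are intentionally not generated — they
    are accepted only as explicit user ranges to ``extract_fragment``.
    """
    residues = s.chain(chain_id)
    ids = [r.res_id for r in residues]
    keys = {k for k in key_residues if k in set(ids)}
    if keys != set(key_residues):
        raise ValueError("key residues must belong to the chain")
    if not keys:
        return []
    candidates = []
    for length in window_lengths:
        for start in range(ids[0], ids[-1] - length + 2):
            end = start + length - 1
            covered = sum(1 for k in keys if start <= k <= end)
            seq = "".join(r.one_letter for r in residues if start <= r.res_id <= end)
            candidates.append(LinearCandidate(
                sequence=seq, source="R1", serial=0,
                ranges=[(start, end)], key_covered=covered,
            ))
    candidates.sort(key=lambda c: (-c.key_covered, len(c.sequence), c.ranges[0][0]))
    return candidates


# ---------------------------------------------------------------------------
# cyclization & naming


def cyclize(c: LinearCandidate, strategy: str) -> CyclicPeptideDesign:
    """Apply one head-to-tail strategy; 1-based renumbering of the result."""
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    if not c.sequence:
        raise ValueError("cannot cyclize an empty sequence")
    n = len(c.sequence)
    if strategy == "CC":
        if c.sequence[0] == "C" or c.sequence[-1] == "C":
            warnings.warn(
                f"sequence {c.sequence!r} already has a terminal Cys; "
                "CC cyclization would stack cysteines"
            )
        seq = "C" + c.sequence + "C"
        closure = f"disulfide(SG1-SG{n + 2})"
    else:
        seq = c.sequence + "GP"
        closure = f"amide(C{n + 2}-N1)"
    return CyclicPeptideDesign(base=c, strategy=strategy, sequence=seq, closure=closure)


def name_design(d: CyclicPeptideDesign) -> str:
    return f"{d.base.source}_{d.strategy}{d.base.serial}"


def parse_design_name(name: str) -> tuple[str, str, int]:
    """Invert ``name_design``: returns (source, strategy, serial)."""
    head, _, tail = name.partition("_")
    source = "α" if head in ("α", "alpha", "a") else head
    if source not in SOURCES:
        raise ValueError(f"unknown source {head!r} in design name {name!r}")
    strategy = tail[:2]
    if strategy not in STRATEGIES or not tail[2:].isdigit():
        raise ValueError(f"cannot parse design name {name!r}")
    return source, strategy, int(tail[2:])


def enumerate_designs(candidates: list[LinearCandidate]) -> list[CyclicPeptideDesign]:
    """Both strategies per candidate: 2x designs, ordered (serial, GP, CC)."""
    designs = []
    for cand in sorted(candidates, key=lambda c: c.serial):
        for strategy in ("GP", "CC"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                designs.append(cyclize(cand, strategy))
    return designs


# ---------------------------------------------------------------------------
# 3-D ring building


def build_cyclic_geometry(
    d: CyclicPeptideDesign,
    template: Structure | None = None,
    n_steps: int = 200,
    tolerance: float = 0.2,
) -> BuildResult:
    """Build ring coordinates and refine the closure bond.

    The backbone is laid out on a circle sized from the per-residue pitch,
    so head and tail start adjacent; the closure atom pair is then relaxed
    by steepest descent (monotone via backtracking) onto the target bond
    length (amide C-N 1.33, disulfide S-S 2.05).  ``template`` is accepted
    for interface compatibility; construction is sequence-driven.
    """
    del template  # sequence-level construction only; see module docs
    s = build_ring_chain(d.sequence, chain_id="A")
    residues = s.chain("A")
    n = len(residues)
    if d.strategy == "CC":
        a1, a2 = residues[0].atom("SG"), residues[-1].atom("SG")
        parents = [residues[0].atom("CB"), residues[-1].atom("CB")]
        bond_targets = [1.81, 1.81]
        target = DISULFIDE_SS_TARGET
        closure_atoms = (f"A:1/SG", f"A:{n}/SG")
    else:
        a1, a2 = residues[-1].atom("C"), residues[0].atom("N")
        parents = [residues[-1].atom("CA"), residues[0].atom("CA")]
        bond_targets = [1.52, 1.46]
        target = AMIDE_CN_TARGET
        closure_atoms = (f"A:{n}/C", f"A:1/N")

    p1, p2 = a1.coords.copy(), a2.coords.copy()
    q1, q2 = parents[0].coords, parents[1].coords

    def objective(x1, x2):
        d_close = np.linalg.norm(x1 - x2)
        e_val = (d_close - target) ** 2
        e_val += (np.linalg.norm(x1 - q1) - bond_targets[0]) ** 2
        e_val += (np.linalg.norm(x2 - q2) - bond_targets[1]) ** 2
        return float(e_val)

    def grad(x1, x2):
        g1 = np.zeros(3)
        g2 = np.zeros(3)
        v = x1 - x2
        dv = np.linalg.norm(v)
        if dv > 1e-9:
            c0 = 2.0 * (dv - target) / dv
            g1 += c0 * v
            g2 -= c0 * v
        for x, q, bt, g in ((x1, q1, bond_targets[0], g1), (x2, q2, bond_targets[1], g2)):
            w = x - q
            dw = np.linalg.norm(w)
            if dw > 1e-9:
                g += 2.0 * (dw - bt) / dw * w
        return g1, g2

    history = [objective(p1, p2)]
    lr = 0.1
    for _ in range(n_steps):
        g1, g2 = grad(p1, p2)
        t1, t2 = p1 - lr * g1, p2 - lr * g2
        e_trial = objective(t1, t2)
        if e_trial <= history[-1]:
            p1, p2 = t1, t2
            history.append(e_trial)
        else:
            lr *= 0.5
            history.append(history[-1])
    a1.coords, a2.coords = p1, p2

    closure_distance = float(np.linalg.norm(p1 - p2))
    residual = abs(closure_distance - target)
    if residual > tolerance:
        raise NonClosureError(
            f"{d.name}: closure residual {residual:.3f} A exceeds {tolerance} A"
        )
    return BuildResult(
        structure=s,
        closure_atoms=closure_atoms,
        closure_distance=closure_distance,
        closure_target=target,
        residual_history=history,
    )
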