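"""Single-trajectory MM-PBSA aggregation and per-residue decomposition.

Complex, receptor and ligand terms are all evaluated on the same complex
coordinates, so internal (bonded) energy differences vanish identically
and the gas-phase deltas reduce to receptor/ligand cross interactions.
Entropy is omitted (the binding energy approximates the enthalpy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..ensemble import Ensemble
from ..forcefield import ParamTable, assign_parameters
from ..structures import Structure
from .pairwise import COULOMB_CONSTANT, coulomb_matrix, lj_matrix
from .pb import make_grid, reaction_field_energy
from .sasa import sasa_areas

__all__ = [
    "PBSettings",
    "EnergyBreakdown",
    "ResidueContribution",
    "PartitionError",
    "nonpolar_solvation",
    "polar_solvation",
    "binding_energy",
    "per_residue_decomposition",
]


class PartitionError(ValueError):
    """Receptor/ligand selections overlap or do not cover the complex."""


def _ensure_params(topology: Structure, table: ParamTable | None) -> Structure:
    """Assign parameters unless the topology already carries a full set."""
    if table is None and all(a.charge is not None for a in topology.atoms()):
        return topology
    topo, _report = assign_parameters(topology, table)
    return topo


@dataclass
class PBSettings:
    """Implicit-solvation and scoring settings.

    Defaults follow the published protocol: dielectrics 1 (solute) / 80
    (solvent), 0.15 M ionic strength, 1.4 Angstrom probe, nonpolar model
    gamma*SASA + beta with gamma = 0.00542 kcal/mol/A^2 and beta = 0.92
    kcal/mol.
    """

    eps_internal: float = 1.0
    eps_external: float = 80.0
    ionic_strength: float = 0.15
    grid_spacing: float = 0.4
    box_margin: float = 8.0
    probe_radius: float = 1.4
    gamma: float = 0.00542
    beta: float = 0.92
    coulomb_constant: float = COULOMB_CONSTANT
    sasa_points: int = 240
    stern_radius: float = 2.0
    temperature: float = 298.15
    include_polar: bool = True

    def __post_init__(self) -> None:
        if not self.eps_external > self.eps_internal >= 1.0:
            raise ValueError("require eps_external > eps_internal >= 1")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")


@dataclass
class EnergyBreakdown:
    """Aggregated binding free energy terms (kcal/mol).

    Identities enforced on unrounded values: e_mm = e_ele + e_vdw + e_int,
    g_solv = g_pb + g_nonp, g_bind = e_mm + g_solv (+ ts_term if present);
    e_int is identically zero under the single-trajectory protocol.
    """

    e_ele: float
    e_vdw: float
    g_pb: float
    g_nonp: float
    e_int: float = 0.0
    ts_term: float | None = None
    sem: dict[str, float] = field(default_factory=dict)

    @property
    def e_mm(self) -> float:
        return self.e_ele + self.e_vdw + self.e_int

    @property
    def g_solv(self) -> float:
        return self.g_pb + self.g_nonp

    @property
    def g_bind(self) -> float:
        total = self.e_mm + self.g_solv
        if self.ts_term is not None:
            total += self.ts_term
        return total

    @classmethod
    def from_components(
        cls,
        e_ele: float,
        e_vdw: float,
        g_pb: float,
        g_nonp: float,
        e_int: float = 0.0,
        ts_term: float | None = None,
    ) -> "EnergyBreakdown":
        return cls(e_ele=e_ele, e_vdw=e_vdw, g_pb=g_pb, g_nonp=g_nonp,
                   e_int=e_int, ts_term=ts_term)

    def as_dict(self) -> dict[str, float]:
        out = {
            "e_ele": self.e_ele,
            "e_vdw": self.e_vdw,
            "e_int": self.e_int,
            "e_mm": self.e_mm,
            "g_pb": self.g_pb,
            "g_nonp": self.g_nonp,
            "g_solv": self.g_solv,
            "g_bind": self.g_bind,
        }
        if self.ts_term is not None:
            out["ts_term"] = self.ts_term
        return out


@dataclass
class ResidueContribution:
    chain_id: str
    res_id: int
    res_name: str
    e_ele: float
    e_vdw: float
    g_pb_share: float
    g_nonp_share: float

    @property
    def total(self) -> float:
        return self.e_ele + self.e_vdw + self.g_pb_share + self.g_nonp_share

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.res_id}"


def nonpolar_solvation(sasa_total: float, settings: PBSettings | None = None) -> float:
    """gamma * SASA + beta (kcal/mol)."""
    settings = settings or PBSettings()
    return settings.gamma * sasa_total + settings.beta


def polar_solvation(structure: Structure, settings: PBSettings | None = None) -> float:
    """PB reaction-field energy of a parameterized structure's heavy atoms."""
    settings = settings or PBSettings()
    coords, charges, _rh, _le, radii, _groups = _heavy_arrays(structure)
    total, _per_atom = reaction_field_energy(
        coords, charges, radii,
        eps_in=settings.eps_internal, eps_out=settings.eps_external,
        ionic_strength=settings.ionic_strength,
        spacing=settings.grid_spacing, margin=settings.box_margin,
        stern=settings.stern_radius, temperature=settings.temperature,
    )
    return total


# ---------------------------------------------------------------------------
# internal array extraction


def _heavy_arrays(structure: Structure):
    """Heavy-atom (coords, q, rmin_half, lj_eps, radius, residue keys)."""
    idx = structure.select(heavy_only=True)
    table = structure.atom_table()
    rows = [table[i] for i in idx]
    coords = np.array([a.coords for _c, _r, a, _i in rows]).reshape(-1, 3)
    for _c, r, a, _i in rows:
        if a.charge is None:
            raise ValueError(f"atom {r.label}/{a.name} is not parameterized")
    q = np.array([a.charge for _c, _r, a, _i in rows], dtype=float)
    rh = np.array([a.lj_rmin_half for _c, _r, a, _i in rows], dtype=float)
    le = np.array([a.lj_epsilon for _c, _r, a, _i in rows], dtype=float)
    rad = np.array([a.solv_radius for _c, _r, a, _i in rows], dtype=float)
    groups = [(c, r.res_id, r.res_name) for c, r, _a, _i in rows]
    return coords, q, rh, le, rad, groups


def _partition_indices(topology: Structure, receptor_chains, ligand_chains):
    rec = set(receptor_chains)
    lig = set(ligand_chains)
    if rec & lig:
        raise PartitionError(f"selections overlap: {sorted(rec & lig)}")
    all_chains = set(topology.chain_ids)
    if rec | lig != all_chains:
        raise PartitionError(
            f"selections {sorted(rec | lig)} do not partition chains {sorted(all_chains)}"
        )
    heavy = topology.select(heavy_only=True)
    table = topology.atom_table()
    rec_mask = np.array([table[i][0] in rec for i in heavy])
    return heavy, rec_mask


def _trailing_frames(n_frames: int, trailing_fraction: float) -> range:
    n_tail = max(1, int(round(trailing_fraction * n_frames)))
    return range(n_frames - n_tail, n_frames)


# ---------------------------------------------------------------------------
# binding energy


def binding_energy(
    e: Ensemble,
    receptor_chains,
    ligand_chains,
    settings: PBSettings | None = None,
    trailing_fraction: float = 1.0,
    table: ParamTable | None = None,
) -> EnergyBreakdown:
    """MM-PBSA binding free energy over the trailing window of an ensemble.

    Per frame: gas-phase cross terms (Coulomb at the internal dielectric,
    12-6 Lennard-Jones), nonpolar term gamma*dSASA - beta (state
    subtraction leaves a single -beta), and a PB polar term solved for the
    complex, receptor and ligand on the complex-sized grid.  Terms are
    averaged and reported with SEM over frames.
    """
    settings = settings or PBSettings()
    topo = _ensure_params(e.topology, table)
    heavy, rec_mask = _partition_indices(topo, receptor_chains, ligand_chains)
    _coords0, q, rh, le, rad, _groups = _heavy_arrays(topo)

    terms = {"e_ele": [], "e_vdw": [], "g_pb": [], "g_nonp": []}
    for k in _trailing_frames(e.n_frames, trailing_fraction):
        frame = e.frames[k][heavy]
        fr = _frame_terms(frame, q, rh, le, rad, rec_mask, settings)
        for key in terms:
            terms[key].append(fr[key])

    means = {k: float(np.mean(v)) for k, v in terms.items()}
    sems = {
        k: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        for k, v in terms.items()
    }
    return EnergyBreakdown(
        e_ele=means["e_ele"], e_vdw=means["e_vdw"],
        g_pb=means["g_pb"], g_nonp=means["g_nonp"],
        e_int=0.0, sem=sems,
    )


def _frame_terms(coords, q, rh, le, rad, rec_mask, settings: PBSettings,
                 per_atom: bool = False) -> dict:
    rec = coords[rec_mask]
    lig = coords[~rec_mask]
    ele_m = coulomb_matrix(rec, q[rec_mask], lig, q[~rec_mask],
                           eps=settings.eps_internal, k=settings.coulomb_constant)
    vdw_m = lj_matrix(rec, rh[rec_mask], le[rec_mask], lig, rh[~rec_mask], le[~rec_mask])

    sasa_c = sasa_areas(coords, rad, settings.probe_radius, settings.sasa_points)
    sasa_r = sasa_areas(rec, rad[rec_mask], settings.probe_radius, settings.sasa_points)
    sasa_l = sasa_areas(lig, rad[~rec_mask], settings.probe_radius, settings.sasa_points)
    d_sasa = sasa_c.total - sasa_r.total - sasa_l.total
    g_nonp = settings.gamma * d_sasa - settings.beta

    if settings.include_polar:
        grid = make_grid(coords, settings.grid_spacing, settings.box_margin)
        kw = dict(
            eps_in=settings.eps_internal, eps_out=settings.eps_external,
            ionic_strength=settings.ionic_strength, spacing=settings.grid_spacing,
            margin=settings.box_margin, stern=settings.stern_radius,
            temperature=settings.temperature, grid=grid,
        )
        pb_c, pa_c = reaction_field_energy(coords, q, rad, **kw)
        pb_r, pa_r = reaction_field_energy(rec, q[rec_mask], rad[rec_mask], **kw)
        pb_l, pa_l = reaction_field_energy(lig, q[~rec_mask], rad[~rec_mask], **kw)
        g_pb = pb_c - pb_r - pb_l
    else:
        g_pb = 0.0
        pa_c = np.zeros(len(coords))
        pa_r = np.zeros(int(rec_mask.sum()))
        pa_l = np.zeros(int((~rec_mask).sum()))

    out = {
        "e_ele": float(ele_m.sum()),
        "e_vdw": float(vdw_m.sum()),
        "g_pb": float(g_pb),
        "g_nonp": float(g_nonp),
    }
    if per_atom:
        n = len(coords)
        pb_share = pa_c.copy()
        pb_share[rec_mask] -= pa_r
        pb_share[~rec_mask] -= pa_l
        d_sasa_atom = sasa_c.per_atom.copy()
        d_sasa_atom[rec_mask] -= sasa_r.per_atom
        d_sasa_atom[~rec_mask] -= sasa_l.per_atom
        out.update(
            ele_matrix=ele_m, vdw_matrix=vdw_m,
            pb_share_per_atom=pb_share,
            nonp_share_per_atom=settings.gamma * d_sasa_atom,
        )
    return out


# ---------------------------------------------------------------------------
# per-residue decomposition


def per_residue_decomposition(
    e: Ensemble,
    receptor_chains,
    ligand_chains,
    settings: PBSettings | None = None,
    trailing_fraction: float = 1.0,
    table: ParamTable | None = None,
) -> list[ResidueContribution]:
    """Per-residue shares of the binding terms, conserving the totals.

    Gas-phase cross-pair energies are halved onto the two partner residues;
    the nonpolar share follows each atom's SASA change (the -beta offset is
    spread evenly over residues); the polar share is the per-atom
    reaction-field energy change.  Residue sums reproduce the
    complex-level terms to numerical precision.
    """
    settings = settings or PBSettings()
    topo = _ensure_params(e.topology, table)
    heavy, rec_mask = _partition_indices(topo, receptor_chains, ligand_chains)
    _coords0, q, rh, le, rad, groups = _heavy_arrays(topo)

    keys = []
    key_index: dict[tuple, int] = {}
    for g in groups:
        if (g[0], g[1]) not in key_index:
            key_index[(g[0], g[1])] = len(keys)
            keys.append(g)
    n_res = len(keys)
    res_of_atom = np.array([key_index[(g[0], g[1])] for g in groups])

    acc = np.zeros((n_res, 4))  # e_ele, e_vdw, g_pb, g_nonp
    frames = list(_trailing_frames(e.n_frames, trailing_fraction))
    rec_atoms = np.nonzero(rec_mask)[0]
    lig_atoms = np.nonzero(~rec_mask)[0]
    for k in frames:
        frame = e.frames[k][heavy]
        fr = _frame_terms(frame, q, rh, le, rad, rec_mask, settings, per_atom=True)
        half_row_ele = 0.5 * fr["ele_matrix"].sum(axis=1)
        half_col_ele = 0.5 * fr["ele_matrix"].sum(axis=0)
        half_row_vdw = 0.5 * fr["vdw_matrix"].sum(axis=1)
        half_col_vdw = 0.5 * fr["vdw_matrix"].sum(axis=0)
        for pos, i in enumerate(rec_atoms):
            acc[res_of_atom[i], 0] += half_row_ele[pos]
            acc[res_of_atom[i], 1] += half_row_vdw[pos]
        for pos, j in enumerate(lig_atoms):
            acc[res_of_atom[j], 0] += half_col_ele[pos]
            acc[res_of_atom[j], 1] += half_col_vdw[pos]
        np.add.at(acc[:, 2], res_of_atom, fr["pb_share_per_atom"])
        np.add.at(acc[:, 3], res_of_atom, fr["nonp_share_per_atom"])
        acc[:, 3] -= settings.beta / n_res
    acc /= len(frames)

    return [
        ResidueContribution(
            chain_id=keys[r][0], res_id=keys[r][1], res_name=keys[r][2],
            e_ele=float(acc[r, 0]), e_vdw=float(acc[r, 1]),
            g_pb_share=float(acc[r, 2]), g_nonp_share=float(acc[r, 3]),
        )
        for r in range(n_res)
    ]
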