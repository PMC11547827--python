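"""End-to-end toy pipeline: simulate -> analyze -> score -> scan -> design -> assay.

A single YAML config drives every stage; all randomness flows from the
config seed, outputs are written with fixed numeric formatting, and the
manifest records inputs, settings, seeds and a sha256 per output file, so
identical config + seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay import fit_kd
from .energetics import PBSettings, binding_energy, per_residue_decomposition
from .ensemble import dccm, hydrogen_bonds, interface_residues, rmsd_series, rmsf
from .peptides import build_cyclic_geometry, enumerate_designs, load_linear_candidates
from .scanning import alanine_scan
from .structures import write_ensemble_models, write_pdb
from .synthetic import (
    BindingCurveSpec,
    EnsembleSpec,
    make_binding_curve,
    make_ensemble,
    make_toy_complex,
)

STAGES = ("simulate", "analyze", "score", "scan", "design", "assay")

_FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (raised before any compute)."""


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    receptor_chains: list[str] = field(default_factory=lambda: ["A"])
    ligand_chains: list[str] = field(default_factory=lambda: ["B"])
    n_res_a: int = 6
    n_res_b: int = 6
    gap: float = 4.5
    seq_a: str | None = None
    seq_b: str | None = None
    n_frames: int = 10
    sigma: float = 0.25
    trailing_fraction: float = 0.5
    interface_cutoff: float = 5.0
    pb: dict = field(default_factory=dict)
    kd_true: float = 0.2
    kd_a_max: float = 1.0
    kd_baseline: float = 0.05
    kd_noise_sd: float = 0.01

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config: {exc}") from exc

    def validate(self) -> None:
        if not self.receptor_chains or not self.ligand_chains:
            raise ConfigError("receptor and ligand selections are both required")
        if set(self.receptor_chains) & set(self.ligand_chains):
            raise ConfigError("receptor and ligand selections overlap")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = PBSettings(**config.pb) if config.pb else PBSettings(
        grid_spacing=0.8, box_margin=5.0
    )

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "settings": asdict(settings),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "status": "complete",
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": [p.name for p in paths],
        }
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    complex_s = make_toy_complex(
        config.n_res_a, config.n_res_b, config.gap, seed=config.seed,
        seq_a=config.seq_a, seq_b=config.seq_b,
    )
    ens = make_ensemble(
        complex_s,
        EnsembleSpec(n_frames=config.n_frames, per_atom_sigma=config.sigma,
                     seed=config.seed, first_frame_is_reference=True),
    )
    complex_path = out_dir / "complex.pdb"
    ens_path = out_dir / "ensemble.pdb"
    write_pdb(complex_s, str(complex_path))
    write_ensemble_models(complex_s, ens.frames, str(ens_path))
    record("simulate", [complex_path, ens_path], t0)

    # -- analyze -----------------------------------------------------------
    t0 = time.perf_counter()
    rmsd = rmsd_series(ens, trailing_fraction=config.trailing_fraction)
    rmsf_series = rmsf(ens)
    iface = interface_residues(complex_s, config.receptor_chains[0],
                               config.ligand_chains[0], config.interface_cutoff)
    hbonds = hydrogen_bonds(ens)
    corr = dccm(ens)
    paths = []
    p = out_dir / "rmsd.csv"
    _write_csv(pd.DataFrame({"frame": np.arange(len(rmsd.values)), "rmsd_A": rmsd.values}), p)
    paths.append(p)
    p = out_dir / "rmsf.csv"
    _write_csv(pd.DataFrame({"residue": rmsf_series.labels, "rmsf_A": rmsf_series.values}), p)
    paths.append(p)
    p = out_dir / "interface.csv"
    rows = [
        {"chain": cid, "res_id": rid}
        for cid, rids in sorted(iface.items()) for rid in sorted(rids)
    ]
    _write_csv(pd.DataFrame(rows, columns=["chain", "res_id"]), p)
    paths.append(p)
    p = out_dir / "hbonds.csv"
    _write_csv(pd.DataFrame(
        [{"donor": h.donor, "acceptor": h.acceptor, "occupancy_pct": h.occupancy}
         for h in hbonds],
        columns=["donor", "acceptor", "occupancy_pct"],
    ), p)
    paths.append(p)
    p = out_dir / "dccm.csv"
    _write_csv(pd.DataFrame(corr), p)
    paths.append(p)
    record("analyze", paths, t0)

    # -- score -------------------------------------------------------------
    t0 = time.perf_counter()
    breakdown = binding_energy(ens, config.receptor_chains, config.ligand_chains,
                               settings, config.trailing_fraction)
    contribs = per_residue_decomposition(ens, config.receptor_chains,
                                         config.ligand_chains, settings,
                                         config.trailing_fraction)
    p1 = out_dir / "mmpbsa.csv"
    rows = [{"term": k, "kcal_per_mol": v} for k, v in breakdown.as_dict().items()]
    for k, v in sorted(breakdown.sem.items()):
        rows.append({"term": f"sem_{k}", "kcal_per_mol": v})
    _write_csv(pd.DataFrame(rows), p1)
    p2 = out_dir / "per_residue.csv"
    _write_csv(pd.DataFrame([
        {"chain": c.chain_id, "res_id": c.res_id, "res_name": c.res_name,
         "e_ele": c.e_ele, "e_vdw": c.e_vdw, "g_pb": c.g_pb_share,
         "g_nonp": c.g_nonp_share, "total": c.total}
        for c in contribs
    ]), p2)
    record("score", [p1, p2], t0)

    # -- scan --------------------------------------------------------------
    t0 = time.perf_counter()
    scan_targets = [
        (cid, rid) for cid, rids in sorted(iface.items()) for rid in sorted(rids)
    ]
    entries = alanine_scan(ens, config.receptor_chains, config.ligand_chains,
                           scan_targets, settings, config.trailing_fraction)
    p = out_dir / "alascan.csv"
    _write_csv(pd.DataFrame([
        {"chain": en.chain_id, "res_id": en.res_id, "res_name": en.res_name,
         "dg_wild": en.dg_wild, "dg_mut": en.dg_mut, "ddg": en.ddg,
         "hotspot": en.is_hotspot}
        for en in entries
    ], columns=["chain", "res_id", "res_name", "dg_wild", "dg_mut", "ddg", "hotspot"]), p)
    record("scan", [p], t0)

    # -- design ------------------------------------------------------------
    t0 = time.perf_counter()
    designs = enumerate_designs(load_linear_candidates())
    p1 = out_dir / "designs.fasta"
    with open(p1, "w") as fh:
        for d in designs:
            closure = "disulfide" if d.strategy == "CC" else "amide"
            fh.write(f">{d.name} cyclization={d.strategy} closure={closure}\n{d.sequence}\n")
    first_cc = next(d for d in designs if d.strategy == "CC")
    built = build_cyclic_geometry(first_cc)
    p2 = out_dir / "cyclic_model.pdb"
    write_pdb(built.structure, str(p2))
    record("design", [p1, p2], t0)

    # -- assay -------------------------------------------------------------
    t0 = time.perf_counter()
    concentrations = [4.0 / 5**i for i in range(8)]
    curve = make_binding_curve(BindingCurveSpec(
        kd_true=config.kd_true, a_max=config.kd_a_max, baseline=config.kd_baseline,
        concentrations=concentrations, noise_sd=config.kd_noise_sd, seed=config.seed,
    ))
    p1 = out_dir / "binding_curve.csv"
    _write_csv(curve, p1)
    fit = fit_kd(curve)
    p2 = out_dir / "kd_fit.json"
    p2.write_text(json.dumps({
        "kd_uM": round(fit.kd, 10), "a_max": round(fit.a_max, 10),
        "baseline": round(fit.baseline, 10), "rss": round(fit.rss, 12),
    }, indent=2, sort_keys=True) + "\n")
    record("assay", [p1, p2], t0)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
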