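"""End-to-end orchestration of the filament-allostery analysis.

A single declarative :class:`AnalysisConfig` drives the full workflow on a
tetramer/octamer pair (real structures or the synthetic analogs):

    selections → GNM correlation profiles → Gō-DMD d_rms profiles →
    buried-interface areas → filament reconstruction

Each stage writes its own TSV/JSON artifacts under ``out_dir`` and the
master report collects every headline number with the exact parameters and
seeds used, so any value in the report can be traced to a stage output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import gnm as gnm_mod
from . import synthetic
from .filament import kink_angle, replicate_filament, screw_decompose, unit_transform
from .godynamics import GoParams, build_go_model, drms_profile, run_dmd
from .interfaces import buried_interface_area
from .selection import (
    ResidueSet,
    interface_residues,
    junction_interface_residues,
    native_contacts,
    pocket_residues,
)
from .structio import Structure, ca_array, extract_ca, read_structure, write_multi_model

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Parameters of a full analysis run.

    With ``synthetic_seed`` set (the default mode), the tetramer/octamer
    pair is generated by the synthetic module; otherwise ``tetramer_path``
    and ``octamer_path`` must point to structure files and the chain groups
    and ligand names must be given explicitly.
    """

    out_dir: str = "filadyn_out"
    seed: int = 0

    # inputs
    synthetic_seed: int | None = 0
    tetramer_path: str | None = None
    octamer_path: str | None = None
    ligand_resnames: tuple[str, ...] = ("LIG",)
    tetramer1_chains: tuple[str, ...] = ("A", "B", "C", "D")
    tetramer2_chains: tuple[str, ...] = ("E", "F", "G", "H")
    linker_chains: tuple[str, ...] = ("S", "T")

    # cutoffs (Å)
    contact_cutoff: float = 7.5
    pocket_expansion: float = 6.0
    interface_cutoff: float = 7.5

    # GNM
    gnm_cutoff: float = 7.5
    gnm_modes: int = 10

    # DMD (scaled-down defaults; production scale is 39 replicas x 6e6 steps)
    dmd_replicas: int = 8
    dmd_steps: int = 200_000
    dmd_temperature: float = 0.5
    dmd_burn_in: float = 2.0 / 6.0
    dmd_snapshot_every: int = 2000
    paper_scale: bool = False

    # SASA
    sasa_points: int = 240

    # filament
    filament_copies: int = 9

    # stage toggles
    run_gnm: bool = True
    run_dmd_stage: bool = True
    run_interfaces: bool = True
    run_filament: bool = True

    def validate(self) -> None:
        for name in ("contact_cutoff", "pocket_expansion", "interface_cutoff",
                     "gnm_cutoff", "dmd_temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.synthetic_seed is None:
            for path in (self.tetramer_path, self.octamer_path):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"input structure not found: {path}")
        if not 0 <= self.dmd_burn_in < 1:
            raise ValueError("dmd_burn_in must be in [0, 1)")

    @property
    def effective_replicas(self) -> int:
        return 39 if self.paper_scale else self.dmd_replicas

    @property
    def effective_steps(self) -> int:
        return 6_000_000 if self.paper_scale else self.dmd_steps


def _chain_index(trace) -> np.ndarray:
    cids = [rid[0] for rid, _ in trace]
    order = sorted(set(cids))
    return np.array([order.index(c) for c in cids], dtype=np.int64)


def _pocket_sets(structure: Structure,
                 config: AnalysisConfig) -> dict[str, ResidueSet]:
    """Pocket residue sets: one per ligand pseudo-atom residue."""
    pockets: dict[str, ResidueSet] = {}
    for cid, res in structure.iter_residues():
        if res.name.upper() in {n.upper() for n in config.ligand_resnames}:
            label = f"{cid}{res.number}"
            pockets[label] = pocket_residues(
                structure, res.atoms, config.pocket_expansion, label="pocket")
    return pockets


def _gnm_stage(structure: Structure, pockets: dict[str, ResidueSet],
               interface: ResidueSet | None, config: AnalysisConfig,
               out: Path, tag: str) -> dict:
    trace = extract_ca(structure)
    ca = ca_array(trace)
    spectrum = gnm_mod.mode_decomposition(
        gnm_mod.build_kirchhoff(ca, config.gnm_cutoff), config.gnm_cutoff)
    profiles = []
    for label, rs in pockets.items():
        if len(rs) < 2:
            logger.warning("%s pocket %s has <2 residues; skipped", tag, label)
            continue
        prof = gnm_mod.correlation_profile(spectrum, rs.indices_in(trace),
                                           config.gnm_modes)
        prof.insert(0, "pocket", label)
        profiles.append(prof)
    table = pd.concat(profiles, ignore_index=True)
    mean_c = (table.groupby("mode")
              .agg(frequency=("frequency", "first"),
                   amplitude=("amplitude", "first"),
                   C_pocket=("C", "mean"))
              .reset_index())
    result = {
        "n_nodes": len(ca),
        "n_zero_modes": spectrum.n_zero,
        "C_pocket_per_mode": mean_c["C_pocket"].tolist(),
        "frequencies": mean_c["frequency"].tolist(),
        "amplitudes": mean_c["amplitude"].tolist(),
    }
    if interface is not None and len(interface) >= 2:
        iprof = gnm_mod.correlation_profile(spectrum, interface.indices_in(trace),
                                            config.gnm_modes, label="C")
        result["C_interface_per_mode"] = iprof["C"].tolist()
    table.to_csv(out / f"gnm_{tag}.tsv", sep="\t", index=False)
    mean_c.to_csv(out / f"gnm_{tag}_mean.tsv", sep="\t", index=False)
    return result


def _dmd_stage(structure: Structure, pockets: dict[str, ResidueSet],
               config: AnalysisConfig, out: Path, tag: str,
               seed_base: int) -> dict:
    trace = extract_ca(structure)
    ca = ca_array(trace)
    cidx = _chain_index(trace)
    contacts = native_contacts(ca, config.contact_cutoff, chain_index=cidx)
    model = build_go_model(ca, contacts, cidx, GoParams())
    trajectories = [
        run_dmd(model, config.effective_steps, config.dmd_temperature,
                seed=seed_base + r, snapshot_every=config.dmd_snapshot_every)
        for r in range(config.effective_replicas)
    ]
    per_pocket = {}
    pooled = []
    for label, rs in pockets.items():
        if len(rs) < 2:
            continue
        summary = drms_profile(trajectories, model, rs.indices_in(trace),
                               config.dmd_burn_in)
        per_pocket[label] = {"mean": summary.mean, "sd": summary.sd,
                             "n_frames": len(summary.values)}
        pooled.append(summary.values)
    values = np.concatenate(pooled)
    np.savetxt(out / f"drms_{tag}.tsv", values, header="drms_A", comments="")
    return {
        "n_beads": model.n_beads,
        "n_contacts": len(contacts),
        "replicas": config.effective_replicas,
        "steps": config.effective_steps,
        "mean_drms": float(values.mean()),
        "sd_drms": float(values.std()),
        "per_pocket": per_pocket,
    }


def _interface_stage(structure: Structure, config: AnalysisConfig,
                     out: Path) -> dict:
    t1 = list(config.tetramer1_chains)
    linkers = list(config.linker_chains)
    t2 = list(config.tetramer2_chains)
    reports = {
        "linker_linker": buried_interface_area(
            structure, linkers[:1], linkers[1:], n_points=config.sasa_points),
        "tetramer1_linkers": buried_interface_area(
            structure, t1, linkers, n_points=config.sasa_points),
        "tetramer1_tetramer2": buried_interface_area(
            structure, t1, t2, n_points=config.sasa_points),
    }
    result = {}
    for label, rep in reports.items():
        rep.to_json(out / f"interface_{label}.json")
        rep.per_residue_table().to_csv(out / f"interface_{label}.tsv",
                                       sep="\t", index=False)
        result[label] = {"area_A2": rep.area,
                         "n_residues_a": len(rep.interface_residues_a)}
    return result


def _filament_stage(structure: Structure, config: AnalysisConfig,
                    out: Path) -> dict:
    t1 = list(config.tetramer1_chains)
    t2 = list(config.tetramer2_chains)
    transform, rmsd = unit_transform(structure, t1, t2)
    screw = screw_decompose(transform)
    screw.to_json(out / "screw_parameters.json")
    kink = kink_angle(structure, t1, t2, "inertia")
    kink_plane = kink_angle(structure, t1, t2, "plane")
    filament = replicate_filament(structure.subset(t1), transform,
                                  config.filament_copies)
    write_multi_model(filament.copies, out / "filament.pdb")
    return {
        "superposition_rmsd_A": rmsd,
        "twist_deg": screw.twist_deg,
        "rise_A": screw.rise,
        "repeats_per_turn": screw.repeats_per_turn,
        "handedness": "right" if screw.handedness > 0 else "left",
        "kink_deg_inertia": kink,
        "kink_deg_plane": kink_plane,
        "copies": config.filament_copies,
        "min_intercopy_ca_A": filament.min_intercopy_ca_distance(),
    }


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline; returns (and writes) the master report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic_seed is not None:
        tetramer, _tt = synthetic.make_tetramer_analog(seed=config.synthetic_seed)
        octamer, _ot = synthetic.make_octamer_analog(seed=config.synthetic_seed)
    else:
        tetramer = read_structure(config.tetramer_path)
        octamer = read_structure(config.octamer_path)

    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    pockets_tet = _pocket_sets(tetramer, config)
    pockets_oct = _pocket_sets(octamer, config)
    interface_set = junction_interface_residues(
        octamer, list(config.tetramer1_chains), list(config.linker_chains),
        list(config.tetramer2_chains), config.interface_cutoff)
    report["stages"]["selection"] = {
        "n_pockets_tetramer": len(pockets_tet),
        "n_pockets_octamer": len(pockets_oct),
        "pocket_sizes_tetramer": {k: len(v) for k, v in pockets_tet.items()},
        "pocket_sizes_octamer": {k: len(v) for k, v in pockets_oct.items()},
        "n_interface_residues": len(interface_set),
    }
    interface_set.to_tsv(out / "interface_residues.tsv", octamer)

    if config.run_gnm:
        report["stages"]["gnm"] = {
            "tetramer": _gnm_stage(tetramer, pockets_tet, None, config, out, "tetramer"),
            "octamer": _gnm_stage(octamer, pockets_oct, interface_set, config,
                                  out, "octamer"),
        }

    if config.run_dmd_stage:
        report["stages"]["dmd"] = {
            "tetramer": _dmd_stage(tetramer, pockets_tet, config, out,
                                   "tetramer", config.seed),
            "octamer": _dmd_stage(octamer, pockets_oct, config, out,
                                  "octamer", config.seed + 1000),
        }

    if config.run_interfaces:
        report["stages"]["interfaces"] = _interface_stage(octamer, config, out)

    if config.run_filament:
        report["stages"]["filament"] = _filament_stage(octamer, config, out)

    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("report written to %s", out / "report.json")
    return report
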