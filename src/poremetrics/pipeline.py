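"""End-to-end analysis pipeline over plain-text inputs.

A run is described by a flat key-value config (YAML or dict): a list of
``stages`` plus per-stage parameters, every one of which has a recorded
default.  Stages execute in the order requested; each writes its tables
under the output directory and contributes a summary to the aggregated
JSON report, which is stamped with the config hash and seed so identical
configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import composition, edge_mechanics, fileio, hydrophobicity
from . import ion_transport, lipid_contacts, pore_geometry, synthetic
from .structures import assign_leaflets, assign_subunits

logger = logging.getLogger(__name__)

#: stage parameter defaults; every analysis default is the convention the
#: rest of the package documents (cutoffs in nm, windows in ns)
DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "n_edges": 2,
    "keep_last_ns": 500.0,
    "discard_ns": 500.0,
    "detection_cutoff_nm": 0.36,
    "release_cutoff_nm": 0.50,
    "temperature_k": 310.15,
    "grid_nm": 0.5,
    "slab_half_width_nm": 1.0,
    "bin_dz_nm": 0.3,
    "n_inner": 99,
    "n_outer": 100,
}


def _cfg(config: dict, key: str, default: Any = None) -> Any:
    if key in config:
        return config[key]
    if key in DEFAULTS:
        return DEFAULTS[key]
    if default is not None:
        return default
    raise KeyError(f"config key {key!r} required and has no default")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_hydrophobicity(config: dict, outdir: Path) -> dict:
    def load(key, builtin):
        path = config.get(key)
        if path is None:
            return builtin
        df = pd.read_csv(path, sep="\t", comment="#")
        return list(zip(df["label"], df["sequence"]))
    strands_a = load("strands_a", hydrophobicity.GSDMD_PORE_FACING_STRANDS)
    strands_b = load("strands_b", hydrophobicity.GSDMA3_PORE_FACING_STRANDS)
    score_a = hydrophobicity.sheet_score(strands_a)
    score_b = hydrophobicity.sheet_score(strands_b)
    excess = hydrophobicity.hydrophilicity_excess(score_a.total, score_b.total)
    rows = [{"sheet": "a", "strand": lab, "sequence": seq, "score_kcal_mol": s}
            for lab, seq, s in score_a.strands]
    rows += [{"sheet": "b", "strand": lab, "sequence": seq, "score_kcal_mol": s}
             for lab, seq, s in score_b.strands]
    fileio.write_tsv(outdir / "hydrophobicity.tsv", pd.DataFrame(rows),
                     comments=["Eisenberg consensus-scale scores, kcal/mol"])
    return {"total_a": round(score_a.total, 10), "total_b": round(score_b.total, 10),
            "hydrophilicity_excess_percent": round(excess, 4)}


def _stage_edge_tension(config: dict, outdir: Path) -> dict:
    series = edge_mechanics.PressureBoxSeries.from_tsv(config["pressure_tsv"])
    keep = config.get("keep_last_ns")
    if keep is not None:
        series = edge_mechanics.retained_window(series, keep)
    result = edge_mechanics.edge_tension(
        series, n_edges=_cfg(config, "n_edges"),
        block_len_ns=config.get("block_len_ns"),
        n_blocks=config.get("n_blocks"))
    return {"gamma_pn": result.gamma, "sem_pn": result.sem,
            "n_edges": result.n_edges, "n_blocks": result.n_blocks}


def _stage_plan_membrane(config: dict, outdir: Path) -> dict:
    plans = {}
    for tag, recipe, n in (("inner", composition.PLASMA_MEMBRANE_INNER,
                            _cfg(config, "n_inner")),
                           ("outer", composition.PLASMA_MEMBRANE_OUTER,
                            _cfg(config, "n_outer"))):
        plan = composition.plan_leaflet(recipe, n)
        plans[tag] = {"counts": plan.counts, "n_total": plan.n_total,
                      "charge": composition.leaflet_charge(plan, recipe)}
    (outdir / "membrane_plan.json").write_text(json.dumps(plans, indent=2))
    return plans


def _stage_synth_pressure(config: dict, outdir: Path) -> dict:
    series, truth = synthetic.synth_pressure_series(
        gamma_true=config.get("gamma_true_pn", 86.4),
        box_xy=config.get("box_xy_nm", 20.0),
        noise_sd=config.get("noise_sd_bar", 0.0),
        n_frames=config.get("n_frames", 1000),
        seed=_cfg(config, "seed"))
    series.to_tsv(outdir / "pressure_series.tsv")
    truth.to_json(outdir / "pressure_series.truth.json")
    return {"fixture": "pressure_series.tsv", **truth.params}


def _stage_contacts(config: dict, outdir: Path) -> dict:
    system, _ = fileio.read_structure(config["structure"])
    frames = list(fileio.read_trajectory(config["trajectory"]))
    if config.get("n_subunits"):
        assign_subunits(system, int(config["n_subunits"]))
    assign_leaflets(system, frames[0])
    cutoff = _cfg(config, "detection_cutoff_nm")
    contacts = lipid_contacts.contacts_over_trajectory(frames, system, cutoff)
    occ = lipid_contacts.occupancy(contacts, system)
    enr = lipid_contacts.species_enrichment(contacts, system)
    fileio.write_tsv(outdir / "occupancy.tsv", occ)
    fileio.write_tsv(outdir / "enrichment.tsv", enr)
    summary = {"n_frames": len(frames),
               "n_contact_pairs": int(sum(len(c) for c in contacts))}
    if config.get("n_subunits"):
        records, per_frame, per_iface = lipid_contacts.bridging_lipids(
            contacts, system, ring_closed=bool(config.get("ring_closed", False)))
        fileio.write_tsv(outdir / "bridging_per_frame.tsv", per_frame)
        fileio.write_tsv(outdir / "bridging_per_interface.tsv", per_iface)
        summary["n_bridge_records"] = len(records)
    return summary


def _stage_permeation(config: dict, outdir: Path) -> dict:
    df = pd.read_csv(config["z_series_tsv"], sep="\t", comment="#")
    ion_cols = [c for c in df.columns if c != "frame"]
    z = df[ion_cols].to_numpy().T
    species = [c.split("_")[0] for c in ion_cols]
    boundaries = ion_transport.SlabBoundaries(
        z_low=float(config["z_low_nm"]), z_high=float(config["z_high_nm"]))
    events, cumulative = ion_transport.permeation_events(
        z, boundaries, lz=float(config["lz_nm"]), species=species)
    fileio.write_tsv(outdir / "permeation_cumulative.tsv", cumulative)
    fileio.write_tsv(outdir / "permeation_events.tsv", pd.DataFrame(
        [{"ion": e.ion, "species": e.species, "direction": e.direction,
          "entry_frame": e.entry_frame, "exit_frame": e.exit_frame}
         for e in events]))
    per_dir = {"up": sum(e.direction == "up" for e in events),
               "down": sum(e.direction == "down" for e in events)}
    return {"n_events": len(events), **per_dir}


def _stage_geometry(config: dict, outdir: Path) -> dict:
    system, frame = fileio.read_structure(config["structure"])
    if config.get("n_subunits"):
        assign_subunits(system, int(config["n_subunits"]))
    summary: dict[str, Any] = {}
    lipids = system.lipid_residues()
    if len(lipids):
        assign_leaflets(system, frame)
        measure = pore_geometry.pore_radius(
            frame, system, slab_half_width=_cfg(config, "slab_half_width_nm"),
            grid=_cfg(config, "grid_nm"))
        summary["pore_diameter_nm"] = None if measure is None else measure.diameter
        if len(set(system.leaflet[lipids])) == 2:   # need a true bilayer
            profile = pore_geometry.deformation_profile(frame, system)
            summary["crown_height_nm"] = profile.crown_height
    if config.get("n_subunits"):
        names = {a.name for a in system.atoms}
        if {"CB", "CT"} <= names:      # hairpin base/tip beads present
            tilts = pore_geometry.hairpin_tilts(frame, system)
            summary["hairpin_tilt_deg_mean"] = float(np.mean(tilts))
        if int(config["n_subunits"]) >= 3:
            centroids = pore_geometry.subunit_centroids(frame, system)
            _, _, rms = pore_geometry.circle_fit(centroids[:, :2])
            summary["circle_rms_nm"] = rms
    (outdir / "geometry.json").write_text(json.dumps(summary, indent=2))
    return summary


STAGES: dict[str, Callable[[dict, Path], dict]] = {
    "hydrophobicity": _stage_hydrophobicity,
    "edge_tension": _stage_edge_tension,
    "plan_membrane": _stage_plan_membrane,
    "synth_pressure": _stage_synth_pressure,
    "contacts": _stage_contacts,
    "permeation": _stage_permeation,
    "geometry": _stage_geometry,
}


def run_pipeline(config: dict, outdir: str | Path = "poremetrics_out") -> dict:
    """Execute the configured stages and return the aggregated report.

    Unknown stage names raise, listing the available stages.  The report
    (also written to ``report.json``) carries the config hash and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    for name in stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; available: "
                             f"{sorted(STAGES)}")
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    report: dict[str, Any] = {
        "config_hash": cfg_hash, "seed": _cfg(config, "seed"), "stages": {}}
    for name in stages:
        t0 = time.perf_counter()
        report["stages"][name] = STAGES[name](config, outdir)
        logger.info("stage %s finished in %.2f s", name,
                    time.perf_counter() - t0)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
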