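"""End-to-end orchestration: simulate -> decode -> hit-call -> cluster -> mirror.

A run is driven by one YAML config that either points at real data (a sample
sheet of per-well FASTQs) or at a simulation block; all thresholds, seeds and
per-stage record counts are echoed into a manifest so a run is reproducible
and auditable.  The top-level seed fans out deterministically to per-stage
child seeds, so any stage rerun in isolation with its recorded child seed
reproduces its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cluster import ClusterParams, hierarchical_cluster, write_families
from .decode import DecodeParams, read_sample_sheet, tally
from .hitcall import HitCallParams, call_hits, hits, write_hit_table
from .library_design import default_design, load_design
from .mirror import synthesis_report, write_candidates
from .simulate import (
    BinderFamily,
    EnrichmentModel,
    ScreenLayout,
    Well,
    chip_like_families,
    default_layout,
    mdm2_like_families,
    plant_families,
    sample_background,
    simulate_screen,
)

logger = logging.getLogger(__name__)

FAMILY_PRESETS = {
    "mdm2_like": mdm2_like_families,
    "chip_like": chip_like_families,
}


class ConfigError(ValueError):
    pass


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _layout_from_config(block: dict) -> ScreenLayout:
    if "wells" in block:
        wells = tuple(
            Well(w["sample_id"], w["role"], float(w["concentration_nM"]),
                 int(w["replicate"]), int(w["reads"]))
            for w in block["wells"]
        )
        return ScreenLayout(wells, float(block.get("spike_in_fraction", 0.05)))
    return default_layout(
        reads_per_well=int(block.get("reads_per_well", 20_000)),
        concentrations_nM=tuple(block.get("concentrations_nM",
                                          (1.0, 10.0, 100.0, 1000.0))),
        n_replicates=int(block.get("n_replicates", 2)),
        n_blanks=int(block.get("n_blanks", 2)),
        spike_in_fraction=float(block.get("spike_in_fraction", 0.05)),
    )


def _families_from_config(block: dict) -> tuple[BinderFamily, ...]:
    preset = block.get("preset")
    if preset is not None:
        if preset not in FAMILY_PRESETS:
            raise ConfigError(
                f"unknown family preset {preset!r}; "
                f"choose from {sorted(FAMILY_PRESETS)}"
            )
        return FAMILY_PRESETS[preset]()
    fams = []
    for f in block.get("families", []):
        fams.append(BinderFamily(
            family_id=f["family_id"], consensus=f["consensus"],
            kd_nM=float(f["kd_nM"]), n_members=int(f.get("n_members", 20)),
            substitution_rate=float(f.get("substitution_rate", 0.1)),
            abundance_scale=float(f.get("abundance_scale", 1.0)),
        ))
    return tuple(fams)


def simulate_stage(config: dict, design, outdir: Path, seed: int):
    """Run the synthetic-screen generator from a config simulation block."""
    sim = config
    layout = _layout_from_config(sim.get("layout", {}))
    model = EnrichmentModel(
        beta=float(sim.get("beta", 50.0)),
        epsilon=float(sim.get("epsilon", 0.0)),
        rc_fraction=float(sim.get("rc_fraction", 0.0)),
        low_quality_tail_fraction=float(sim.get("low_quality_tail_fraction", 0.0)),
    )
    s_bg, s_plant, s_screen = child_seeds(seed, 3)
    population = sample_background(
        design,
        n_sequences=int(sim.get("n_background", 5_000)),
        lognormal_mu=float(sim.get("lognormal_mu", 0.0)),
        lognormal_sigma=float(sim.get("lognormal_sigma", 1.0)),
        rng=s_bg,
    )
    families = _families_from_config(sim)
    truth = None
    if families:
        population, truth = plant_families(population, families, design,
                                           rng=s_plant)
    else:
        import pandas as pd
        truth = pd.DataFrame(columns=["peptide", "family_id", "kd_nM"])
    return simulate_screen(population, truth, layout, model, design,
                           outdir, seed=s_screen)


def run_all(config: dict | str | Path, outdir: str | Path,
            seed: int | None = None) -> Path:
    """Run the full pipeline from a config; returns the output directory.

    Identical config + seed gives byte-identical outputs.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    design_path = config.get("design")
    design = load_design(design_path) if design_path else default_design()

    has_sheet = "sample_sheet" in config
    has_sim = "simulation" in config
    if has_sheet == has_sim:
        raise ConfigError("config needs exactly one of sample_sheet/simulation")
    if seed is None:
        seed = config.get("seed")
    if has_sim and seed is None:
        raise ConfigError("simulation requires a seed")
    seed = int(seed) if seed is not None else 0

    manifest: dict = {
        "version": __version__,
        "design": design.name,
        "seed": seed,
        "stages": {},
    }

    if has_sim:
        sim_dir = outdir / "simulated"
        screen = simulate_stage(config["simulation"], design, sim_dir, seed)
        sheet_path = screen.sample_sheet
        manifest["stages"]["simulate"] = {
            "outdir": str(sim_dir),
            "n_wells": len(screen.fastq_paths),
        }
    else:
        sheet_path = Path(config["sample_sheet"])

    sheet = read_sample_sheet(sheet_path)
    dec = DecodeParams(**config.get("decode", {}))
    counts = tally(sheet, design, dec)
    if not counts.conservation_ok():  # pragma: no cover - internal invariant
        raise RuntimeError("decode conservation violated")
    counts.to_tsv(outdir / "counts.tsv", outdir / "rejections.tsv")
    manifest["stages"]["decode"] = {
        "params": asdict(dec),
        "total_reads": {s: int(v) for s, v in counts.total_reads.items()},
        "assigned": {s: int(v) for s, v in counts.counts.sum(axis=0).items()},
        "spike": {s: int(v) for s, v in counts.spike_counts.items()},
        "rejected": {s: int(v) for s, v in counts.rejected.sum(axis=0).items()},
        "n_unique_peptides": int(len(counts.counts)),
    }

    hc = HitCallParams(**config.get("hitcall", {}))
    table = call_hits(counts, sheet, hc)
    write_hit_table(table, outdir / "hits.tsv", hc)
    hit_df = hits(table)
    manifest["stages"]["hitcall"] = {
        "params": asdict(hc),
        "n_hits": int(len(hit_df)),
    }

    cl = ClusterParams(**config.get("cluster", {}))
    if len(hit_df) > 0:
        fams = hierarchical_cluster(
            list(hit_df.index), design,
            hs=hit_df["hit_strength"], params=cl,
        )
        write_families(fams, outdir)
        n_proper = len(fams.proper_families)
        manifest["stages"]["cluster"] = {
            "params": asdict(cl),
            "n_families": n_proper,
            "n_singletons": len(fams.families) - n_proper,
        }
        mirror_cfg = config.get("mirror", {})
        report = synthesis_report(
            fams,
            substitute_met_nle=bool(mirror_cfg.get("met_to_nle", True)),
            staple_positions=design.staple_positions,
        )
        write_candidates(report, outdir)
        manifest["stages"]["mirror"] = {"n_candidates": int(len(report))}
    else:
        (outdir / "families.tsv").write_text("peptide\tfamily_id\thit_strength\n")
        manifest["stages"]["cluster"] = {"params": asdict(cl), "n_families": 0,
                                         "n_singletons": 0}
        manifest["stages"]["mirror"] = {"n_candidates": 0}

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir
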