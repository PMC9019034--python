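"""End-to-end orchestration: simulate -> design -> process -> junctions ->
matrices, as one reproducible, logged run."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .core import BinGrid, TargetRegion
from .junctions import (JunctionTable, call_junctions, dedup_junctions,
                        filter_junctions, write_pairs)
from .matrix import bin_junctions, ice_balance, write_matrix
from .reads import merge_pairs, place_segments, split_chimeric, trim_adapters
from .simulate import SimConfig, simulate_genome, simulate_library, write_library

__all__ = ["RunConfig", "run_pipeline", "process_reads"]

_STAGE_PARAMS = {
    "min_overlap": 10,
    "max_mismatch_density": 0.25,
    "min_score": 20.0,
    "min_alignment_length": 20,
    "min_identity": 0.9,
    "max_query_gap": 5,
    "wobble": 2,
    "min_distance_density": 10,
    "min_distance_matrix": 0,
    "binsize": 500,
    "ice_max_iter": 200,
    "ice_tol": 1e-5,
}


@dataclass
class RunConfig:
    """Flat run configuration; every field is echoed into the run manifest."""

    out_dir: str
    seed: int = 0
    sample: str = "sample"
    fastq_r1: str | None = None
    fastq_r2: str | None = None
    genome_fasta: str | None = None
    regions_bed: str | None = None
    simulate: bool = True
    sim: SimConfig | None = None
    params: dict = field(default_factory=lambda: dict(_STAGE_PARAMS))

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(_STAGE_PARAMS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_STAGE_PARAMS)
        merged.update(self.params)
        self.params = merged


def process_reads(
    pairs,
    regions: list[TargetRegion],
    genome: dict[str, str],
    params: dict | None = None,
) -> tuple[dict, dict]:
    """FASTQ pairs -> placed segments, with per-stage counters."""
    p = dict(_STAGE_PARAMS)
    if params:
        p.update(params)
    trimmed, trim_stats = trim_adapters(pairs)
    merged, merge_stats = merge_pairs(
        trimmed, min_overlap=p["min_overlap"],
        max_mismatch_density=p["max_mismatch_density"],
    )
    segments, split_stats = split_chimeric(
        merged, regions,
        min_score=p["min_score"],
        min_length=p["min_alignment_length"],
        min_identity=p["min_identity"],
    )
    read_seqs = {r.id: r.sequence for r in merged}
    placed, place_stats = place_segments(segments, read_seqs, genome)
    stats = {
        "trim": trim_stats,
        "merge": merge_stats,
        "split": split_stats,
        "place": place_stats,
    }
    return placed, read_seqs, stats


def junctions_from_segments(
    placed: dict, params: dict, genome: dict[str, str] | None = None,
    reads: dict[str, str] | None = None, sample: str = "sample",
) -> tuple[JunctionTable, JunctionTable]:
    """Call, dedup, and distance-filter junctions.

    Returns (table for matrices, table for density plots); the two differ
    only in their minimum-distance threshold.
    """
    raw = call_junctions(placed, max_gap=params["max_query_gap"],
                         genome=genome, reads=reads)
    table = dedup_junctions(raw, wobble=params["wobble"], sample=sample)
    matrix_table = filter_junctions(table, params["min_distance_matrix"])
    density_table = filter_junctions(table, params["min_distance_density"])
    return matrix_table, density_table


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write a machine-readable manifest.

    Reruns with the same configuration and inputs reproduce byte-identical
    junction tables and matrices.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "sample": config.sample,
        "params": config.params,
        "stages": {},
    }

    if config.simulate:
        sim = config.sim or SimConfig(seed=config.seed)
        manifest["sim_config"] = dataclasses.asdict(sim)
        genome, regions = simulate_genome(
            sim.seed, sim.genome_length, sim.masked_fraction
        )
        pairs, truth = simulate_library(sim, regions, genome)
        paths = write_library(out, pairs, truth, genome, regions)
        manifest["stages"]["simulate"] = {
            "n_read_pairs": len(pairs),
            "n_truth_records": len(truth),
            "outputs": {k: str(v) for k, v in paths.items()},
        }
    else:
        for key in ("fastq_r1", "fastq_r2", "genome_fasta", "regions_bed"):
            path = getattr(config, key)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"missing input {key}: {path}")
        genome = mio.read_fasta(config.genome_fasta)
        regions = mio.load_regions(config.genome_fasta, config.regions_bed)
        pairs = list(
            zip(mio.read_fastq(config.fastq_r1), mio.read_fastq(config.fastq_r2))
        )

    placed, read_seqs, stats = process_reads(pairs, regions, genome, config.params)
    manifest["stages"].update(stats)

    matrix_table, density_table = junctions_from_segments(
        placed, config.params, genome, read_seqs, config.sample
    )
    write_pairs(out / f"{config.sample}_junctions.pairs.tsv", matrix_table)
    manifest["stages"]["junctions"] = {
        **matrix_table.stage_counts,
        "density_filtered": len(density_table),
    }

    matrices = {}
    for region in regions:
        grid = BinGrid(region, config.params["binsize"])
        mat, bin_stats = bin_junctions(matrix_table, grid)
        if mat.counts.sum() == 0:
            manifest["stages"][f"matrix_{region.name}"] = {
                **bin_stats, "skipped": "no junctions in region"}
            continue
        mat = ice_balance(
            mat, config.params["ice_max_iter"], config.params["ice_tol"]
        )
        write_matrix(mat, out / f"{config.sample}_{region.name}")
        matrices[region.name] = mat
        manifest["stages"][f"matrix_{region.name}"] = {
            **bin_stats,
            "raw_mass": float(mat.counts.sum()),
            "masked_bins": int(mat.mask.sum()),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return {
        "manifest": manifest,
        "regions": regions,
        "genome": genome,
        "matrix_table": matrix_table,
        "density_table": density_table,
        "matrices": matrices,
    }
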