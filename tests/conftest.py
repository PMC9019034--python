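import numpy as np
import pytest

from mcctools.core import GenomicInterval, TargetRegion
from mcctools.pipeline import _STAGE_PARAMS, junctions_from_segments, process_reads
from mcctools.simulate import SimConfig, simulate_genome, simulate_library


def random_region(seed: int, length: int = 3000, chrom: str = "chrT",
                  start: int = 0, name: str = "reg") -> TargetRegion:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return TargetRegion(name, GenomicInterval(chrom, start, start + length), seq)


@pytest.fixture(scope="session")
def small_sim():
    """Error-free, duplicate-free 12 kb library; fast enough for unit tests."""
    cfg = SimConfig(
        seed=3, genome_length=12_000, n_ligation_events=400,
        error_rate=0.0, pcr_duplicate_rate=0.0,
        anchor_pairs=((2_000, 4_000, 50.0),), max_distance=4_000,
    )
    genome, regions = simulate_genome(cfg.seed, cfg.genome_length,
                                      cfg.masked_fraction)
    pairs, truth = simulate_library(cfg, regions, genome)
    return cfg, genome, regions, pairs, truth


@pytest.fixture(scope="session")
def small_processed(small_sim):
    cfg, genome, regions, pairs, truth = small_sim
    placed, read_seqs, stats = process_reads(pairs, regions, genome)
    table, density = junctions_from_segments(
        placed, _STAGE_PARAMS, genome, read_seqs
    )
    return {
        "cfg": cfg, "genome": genome, "regions": regions, "truth": truth,
        "placed": placed, "read_seqs": read_seqs, "stats": stats,
        "table": table, "density": density,
    }


@pytest.fixture(scope="session")
def full_sim_processed():
    """The full study conditions: 50 kb genome, 20,000 error-free ligation
    events, 10% PCR duplication, one 50x anchor pair."""
    cfg = SimConfig(seed=1, error_rate=0.0)
    genome, regions = simulate_genome(cfg.seed, cfg.genome_length,
                                      cfg.masked_fraction)
    pairs, truth = simulate_library(cfg, regions, genome)
    placed, read_seqs, stats = process_reads(pairs, regions, genome)
    table, density = junctions_from_segments(
        placed, _STAGE_PARAMS, genome, read_seqs
    )
    return {
        "cfg": cfg, "genome": genome, "regions": regions, "truth": truth,
        "placed": placed, "stats": stats, "table": table, "density": density,
    }
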