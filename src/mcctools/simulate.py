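"""Synthetic tiled-capture MCC library generator with ground truth.

Emulates the physical library: MNase digestion to mono-nucleosome-sized
(~180 bp) fragments, proximity ligation of exactly two fragments per
molecule with a distance-decaying contact probability plus optional
enriched anchor pairs (loop-like contacts), sonication to ~200 bp,
PCR duplication with +/-2 bp end wobble, and 150 bp paired-end sequencing
with substitution errors.  Every sequenced molecule is recorded in a truth
table carrying the exact junction coordinates and orientations, so the
whole downstream pipeline can be validated against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomicInterval, TargetRegion
from .io import FastqRecord, write_fasta, write_bed, write_fastq

__all__ = ["SimConfig", "simulate_genome", "simulate_library", "write_library"]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TRUTH_COLUMNS = [
    "read_id",
    "chrom1",
    "pos1",
    "strand1",
    "chrom2",
    "pos2",
    "strand2",
    "sonication_left",
    "sonication_right",
    "is_pcr_duplicate",
    "dup_of",
    "junction_in_read",
]

# Standard Illumina TruSeq adapter read-through sequences (R1 / R2).
ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SimConfig:
    """Library-simulation parameters.

    Defaults describe a desk-scale tiled-capture MCC experiment: a 50 kb
    toy genome with two capture regions, 20,000 ligation events, ~180 bp
    MNase fragments, sonication to ~200 bp, 150 bp paired-end reads, one
    strongly (50x) enriched anchor pair inside the first region, ~20% of
    events off target, 10% PCR duplication, and a contact-frequency decay
    P(d) ~ d**-1.  The default anchor coordinates sit at the centres of
    500 bp bins so the designed loop signal is not split across bin pairs
    when evaluated at that resolution.
    """

    seed: int = 0
    genome_length: int = 50_000
    n_ligation_events: int = 20_000
    fragment_len_mean: float = 180.0
    fragment_len_sd: float = 25.0
    sonication_mean: float = 200.0
    sonication_sd: float = 30.0
    read_len: int = 150
    pcr_duplicate_rate: float = 0.1
    error_rate: float = 0.001
    anchor_pairs: tuple[tuple[int, int, float], ...] = ((8_250, 16_250, 50.0),)
    decay_exponent: float = 1.0
    off_target_fraction: float = 0.2
    min_distance: int = 30
    max_distance: int | None = None
    masked_fraction: float = 0.05
    anchor_jitter_sd: float = 35.0
    anchor_window: int = 200
    min_fragment_len: int = 50
    max_fragment_len: int = 400
    junction_flank: int = 20

    def __post_init__(self) -> None:
        for name in ("pcr_duplicate_rate", "error_rate", "off_target_fraction",
                     "masked_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fragment_len_mean <= 0:
            raise ValueError("fragment_len_mean must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")

    @property
    def dmax(self) -> int:
        return self.max_distance or self.genome_length // 2


def simulate_genome(
    seed: int,
    genome_length: int,
    masked_fraction: float = 0.0,
    chrom: str = "chrS",
) -> tuple[dict[str, str], list[TargetRegion]]:
    """Random toy genome with soft-masked stretches and two target regions.

    The two capture regions span [0.1L, 0.4L) and [0.6L, 0.9L); the
    remaining 40% of the genome provides off-target sequence.  Masked
    stretches of 200-800 bp are lowercased until the requested fraction is
    reached (within one stretch length).  Deterministic for a fixed seed.
    """
    if not 0.0 <= masked_fraction <= 1.0:
        raise ValueError("masked_fraction outside [0, 1]")
    if genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb for meaningful tests")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=genome_length)
    if masked_fraction > 0:
        masked = np.zeros(genome_length, dtype=bool)
        while masked.sum() < masked_fraction * genome_length:
            start = int(rng.integers(0, genome_length))
            length = int(rng.integers(200, 801))
            masked[start : start + length] = True
        low = np.char.lower(seq)
        seq = np.where(masked, low, seq)
    genome_seq = "".join(seq)
    genome = {chrom: genome_seq}
    L = genome_length
    regions = [
        TargetRegion(
            "targetA",
            GenomicInterval(chrom, int(0.1 * L), int(0.4 * L)),
            genome_seq[int(0.1 * L) : int(0.4 * L)],
        ),
        TargetRegion(
            "targetB",
            GenomicInterval(chrom, int(0.6 * L), int(0.9 * L)),
            genome_seq[int(0.6 * L) : int(0.9 * L)],
        ),
    ]
    return genome, regions


# ---------------------------------------------------------------------------
# distance-decay sampling


def _decay_cdf(x: float, alpha: float, dmin: float, dmax: float) -> float:
    """CDF of the truncated power law P(d) ~ d**-alpha on [dmin, dmax]."""
    x = min(max(x, dmin), dmax)
    if abs(alpha - 1.0) < 1e-9:
        return math.log(x / dmin) / math.log(dmax / dmin)
    a = 1.0 - alpha
    return (x**a - dmin**a) / (dmax**a - dmin**a)


def _sample_distances(
    rng: np.random.Generator, n: int, alpha: float, dmin: float, dmax: float
) -> np.ndarray:
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-9:
        return dmin * (dmax / dmin) ** u
    a = 1.0 - alpha
    return (u * (dmax**a - dmin**a) + dmin**a) ** (1.0 / a)


# ---------------------------------------------------------------------------
# library simulation


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _homology_shift(chrom_seq: str, j1: int, o1: str, j2: int, o2: str,
                    cap: int = 30) -> int:
    """Length of the micro-homology run immediately left of the junction.

    A ligation junction is ambiguous within the run of bases where the two
    fragments' flanking genomic sequences agree in read orientation: any
    split inside the run yields the same read.  Junction coordinates are
    therefore reported at the leftmost (read-wise) edge of this zone, the
    analogue of left-aligning an indel; this function returns the shift.
    """
    L = len(chrom_seq)
    e = 0
    while e < cap:
        if o1 == "+":
            pa = j1 - 1 - e
            ca = chrom_seq[pa].upper() if pa >= 0 else None
        else:
            pa = j1 + e
            ca = _COMP[chrom_seq[pa].upper()] if pa < L else None
        if o2 == "+":
            pb = j2 - 1 - e
            cb = chrom_seq[pb].upper() if pb >= 0 else None
        else:
            pb = j2 + e
            cb = _COMP[chrom_seq[pb].upper()] if pb < L else None
        if ca is None or cb is None or ca != cb:
            break
        e += 1
    return e


@dataclass
class _Molecule:
    """One ligated, sonicated, sequenced molecule plus its truth record."""

    read_id: str
    r1: FastqRecord
    r2: FastqRecord
    truth: dict


def _truncnorm(rng, mean, sd, lo, hi) -> int:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return int(round(v))
    return int(min(max(mean, lo), hi))


def simulate_library(
    config: SimConfig,
    regions: list[TargetRegion],
    genome: dict[str, str],
) -> tuple[list[tuple[FastqRecord, FastqRecord]], pd.DataFrame]:
    """Simulate read pairs and the matching truth table.

    Each ligation event joins two MNase fragments in a random relative
    orientation; the chimeric molecule is sonicated to a ~200 bp window
    chosen uniformly (so the junction is retained with probability
    proportional to its overlap with the window) and sequenced from both
    ends.  Anchor-pair events are added on top of the distance-decay
    background at ``enrichment`` times the expected background count in a
    small window around the anchor coordinates.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom = regions[0].chrom
    chrom_seq = genome[chrom]
    L = len(chrom_seq)
    margin = cfg.max_fragment_len + 10

    target_len = sum(len(r) for r in regions)
    region_bounds = [(r.start, r.end) for r in regions]
    region_weights = np.array([len(r) for r in regions], dtype=float)
    region_weights /= region_weights.sum()

    # how many events each anchor pair receives: enrichment x the expected
    # background count in an anchor_window x anchor_window neighbourhood
    n_total = cfg.n_ligation_events
    w = cfg.anchor_window
    anchor_counts = []
    for (pa, pb, enrich) in cfg.anchor_pairs or ():
        d = abs(pb - pa)
        p_dist = _decay_cdf(d + w / 2, cfg.decay_exponent, cfg.min_distance, cfg.dmax) - \
            _decay_cdf(d - w / 2, cfg.decay_exponent, cfg.min_distance, cfg.dmax)
        p_pair = (w / target_len) * p_dist  # both orderings combined
        anchor_counts.append(int(round(enrich * n_total * p_pair)))
    n_anchor = sum(anchor_counts)
    n_background = max(n_total - n_anchor, 0)

    # junction coordinate pairs (j1, j2) for every event
    events: list[tuple[int, int]] = []
    for (pa, pb, _), cnt in zip(cfg.anchor_pairs or (), anchor_counts):
        j1 = np.rint(pa + rng.normal(0, cfg.anchor_jitter_sd, cnt)).astype(int)
        j2 = np.rint(pb + rng.normal(0, cfg.anchor_jitter_sd, cnt)).astype(int)
        events.extend(zip(j1.tolist(), j2.tolist()))

    n_off = int(round(cfg.off_target_fraction * n_background))
    dists = _sample_distances(
        rng, n_background, cfg.decay_exponent, cfg.min_distance, cfg.dmax
    )
    signs = rng.choice([-1, 1], size=n_background)
    for i in range(n_background):
        if i < n_off:
            # first junction point outside every target region
            while True:
                j1 = int(rng.integers(margin, L - margin))
                if not any(s <= j1 < e for s, e in region_bounds):
                    break
        else:
            ridx = int(rng.choice(len(regions), p=region_weights))
            s, e = region_bounds[ridx]
            j1 = int(rng.integers(s, e))
        j2 = j1 + int(signs[i]) * int(round(dists[i]))
        if not margin <= j2 < L - margin:
            j2 = j1 - int(signs[i]) * int(round(dists[i]))
        j2 = int(min(max(j2, margin), L - margin - 1))
        events.append((j1, j2))

    order = rng.permutation(len(events))
    molecules: list[_Molecule] = []
    for serial, idx in enumerate(order.tolist()):
        j1, j2 = events[idx]
        molecules.append(
            _build_molecule(cfg, rng, chrom, chrom_seq, j1, j2, f"r{serial:06d}")
        )

    # PCR duplicates: resample the same molecule window with <=2 bp end wobble
    n_mol = len(molecules)
    r = cfg.pcr_duplicate_rate
    n_dup = int(round(n_mol * r / (1.0 - r))) if r > 0 else 0
    dup_templates = rng.integers(0, n_mol, size=n_dup) if n_dup else []
    duplicates = []
    for k, t in enumerate(dup_templates):
        tmpl = molecules[int(t)]
        duplicates.append(_duplicate_molecule(cfg, rng, tmpl, k))
    molecules.extend(duplicates)

    pairs = [(m.r1, m.r2) for m in molecules]
    truth = pd.DataFrame([m.truth for m in molecules], columns=TRUTH_COLUMNS)
    return pairs, truth


def _build_molecule(cfg, rng, chrom, chrom_seq, j1, j2, read_id):
    L = len(chrom_seq)
    margin = cfg.max_fragment_len + 10
    j1 = int(min(max(j1, margin), L - margin - 1))
    j2 = int(min(max(j2, margin), L - margin - 1))
    len1 = _truncnorm(rng, cfg.fragment_len_mean, cfg.fragment_len_sd,
                      cfg.min_fragment_len, cfg.max_fragment_len)
    len2 = _truncnorm(rng, cfg.fragment_len_mean, cfg.fragment_len_sd,
                      cfg.min_fragment_len, cfg.max_fragment_len)
    o1 = "+" if rng.random() < 0.5 else "-"
    o2 = "+" if rng.random() < 0.5 else "-"
    # fragment 1: junction-proximal end sits at the molecule-right side
    if o1 == "+":
        f1s, f1e = j1 - len1, j1
    else:
        f1s, f1e = j1, j1 + len1
    # fragment 2: junction-proximal end sits at the molecule-left side
    if o2 == "+":
        f2s, f2e = j2, j2 + len2
    else:
        f2s, f2e = j2 - len2, j2
    part1 = chrom_seq[f1s:f1e].upper()
    part2 = chrom_seq[f2s:f2e].upper()
    if o1 == "-":
        part1 = revcomp(part1)
    if o2 == "-":
        part2 = revcomp(part2)
    molecule = part1 + part2

    son_len = _truncnorm(rng, cfg.sonication_mean, cfg.sonication_sd,
                         60, len(molecule))
    ws = int(rng.integers(0, len(molecule) - son_len + 1))
    we = ws + son_len
    # canonical (leftmost) junction coordinates under micro-homology
    e = _homology_shift(chrom_seq, j1, o1, j2, o2)
    j1c = j1 - e if o1 == "+" else j1 + e
    j2c = j2 - e if o2 == "+" else j2 + e
    return _emit(cfg, rng, chrom, read_id, molecule, ws, we,
                 (f1s, f1e, o1), (f2s, f2e, o2), len1, j1c, j2c,
                 is_dup=False, dup_of="")


def _duplicate_molecule(cfg, rng, tmpl, k):
    t = tmpl.truth
    ws = t["_ws"] + int(rng.integers(-2, 3))
    we = t["_we"] + int(rng.integers(-2, 3))
    ws = max(ws, 0)
    we = min(we, len(t["_molecule"]))
    if we - ws < 40:
        ws, we = t["_ws"], t["_we"]
    return _emit(
        cfg, t["_rng"], t["_chrom"], f"{tmpl.read_id}.dup{k}", t["_molecule"],
        ws, we, t["_frag1"], t["_frag2"], t["_len1"], t["pos1_raw"],
        t["pos2_raw"], is_dup=True, dup_of=tmpl.read_id,
    )


def _genomic_at(m, frag1, frag2, len1):
    """Genomic coordinate of molecule offset ``m`` (boundary convention)."""
    f1s, f1e, o1 = frag1
    f2s, f2e, o2 = frag2
    if m <= len1:
        return f1s + m if o1 == "+" else f1e - m
    m2 = m - len1
    return f2s + m2 if o2 == "+" else f2e - m2


def _emit(cfg, rng, chrom, read_id, molecule, ws, we,
          frag1, frag2, len1, j1, j2, is_dup, dup_of):
    window = molecule[ws:we]
    S = len(window)
    rl = cfg.read_len

    def make_read(seq: str, adapter: str) -> tuple[str, str]:
        if len(seq) < rl:  # short insert: adapter read-through, then pad
            seq = (seq + adapter + "G" * rl)[:rl]
        else:
            seq = seq[:rl]
        qual = ["F"] * len(seq)
        if cfg.error_rate > 0:
            hits = np.nonzero(rng.random(len(seq)) < cfg.error_rate)[0]
            if hits.size:
                s = list(seq)
                for p in hits.tolist():
                    s[p] = rng.choice([b for b in "ACGT" if b != s[p].upper()])
                    qual[p] = "0"
                seq = "".join(s)
        return seq, "".join(qual)

    s1, q1 = make_read(window, ADAPTER_R1)
    s2, q2 = make_read(revcomp(window), ADAPTER_R2)

    # junction is usable if one sequenced stretch covers >= flank bp on
    # either side of it
    flank = cfg.junction_flank
    jw = len1 - ws  # junction offset in window coordinates
    if S <= 2 * rl:
        covered = [(0, S)]
    else:
        covered = [(0, rl), (S - rl, S)]
    junction_in_read = any(a + flank <= jw <= b - flank for a, b in covered)

    son_left = _genomic_at(ws, frag1, frag2, len1)
    son_right = _genomic_at(we, frag1, frag2, len1)
    o1, o2 = frag1[2], frag2[2]
    truth = {
        "read_id": read_id,
        "chrom1": chrom,
        "pos1": j1,
        "strand1": o1,
        "chrom2": chrom,
        "pos2": j2,
        "strand2": o2,
        "sonication_left": son_left,
        "sonication_right": son_right,
        "is_pcr_duplicate": is_dup,
        "dup_of": dup_of,
        "junction_in_read": junction_in_read,
        # private fields used to emit PCR duplicates; dropped on output
        "_molecule": molecule,
        "_ws": ws,
        "_we": we,
        "_frag1": frag1,
        "_frag2": frag2,
        "_len1": len1,
        "_chrom": chrom,
        "_rng": rng,
        "pos1_raw": j1,
        "pos2_raw": j2,
    }
    return _Molecule(
        read_id,
        FastqRecord(read_id, s1, q1),
        FastqRecord(read_id, s2, q2),
        truth,
    )


def write_library(
    out_dir: str | Path,
    pairs: list[tuple[FastqRecord, FastqRecord]],
    truth: pd.DataFrame,
    genome: dict[str, str] | None = None,
    regions: list[TargetRegion] | None = None,
    prefix: str = "sim",
) -> dict[str, Path]:
    """Write paired FASTQ, the truth TSV, and optionally FASTA + BED."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "r1": out_dir / f"{prefix}_R1.fastq",
        "r2": out_dir / f"{prefix}_R2.fastq",
        "truth": out_dir / f"{prefix}_truth.tsv",
    }
    write_fastq(paths["r1"], (p[0] for p in pairs))
    write_fastq(paths["r2"], (p[1] for p in pairs))
    truth[TRUTH_COLUMNS].to_csv(paths["truth"], sep="\t", index=False)
    if genome is not None:
        paths["fasta"] = out_dir / f"{prefix}_genome.fa"
        write_fasta(paths["fasta"], genome)
    if regions is not None:
        paths["bed"] = out_dir / f"{prefix}_regions.bed"
        write_bed(paths["bed"], ((r.interval, [r.name]) for r in regions))
    return paths
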