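"""Ligation-junction reconstruction, wobble deduplication, and filtering.

A junction is evidenced by two consecutive segments of one read whose
read-space coordinates are less than 5 bp apart; its genomic coordinates
are the junction-proximal fragment ends, taking read orientation into
account.  PCR duplicates share both the ligation junction and the
sonication (molecule outer) ends up to a +/-2 bp wobble and are collapsed
by single-linkage clustering on that relation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .reads import ReadSegment
from .io import PAIRS_COLUMNS

__all__ = [
    "LigationJunction",
    "JunctionTable",
    "call_junctions",
    "dedup_junctions",
    "dedup_brute_force",
    "filter_junctions",
    "write_pairs",
    "read_pairs",
]

MAX_QUERY_GAP = 5  # fragment ends must be < 5 bp apart in the read
WOBBLE = 2  # +/- bp tolerated on every coordinate during deduplication


@dataclass(frozen=True)
class LigationJunction:
    """An oriented junction between two genomic positions.

    ``pos1`` is the junction-proximal end of the first fragment (g_end for
    a '+' segment, g_start for '-'); ``pos2`` symmetrically for the second.
    Partners are stored in canonical order ((chrom1, pos1) <= (chrom2,
    pos2)); ``sonication_left``/``sonication_right`` are the outer genomic
    ends of the sequenced molecule on the respective partner's side and
    are swapped along with the partners.
    """

    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sonication_left: int
    sonication_right: int

    @property
    def distance(self) -> int:
        if self.chrom1 != self.chrom2:
            return -1
        return abs(self.pos2 - self.pos1)

    def canonical(self) -> "LigationJunction":
        if (self.chrom2, self.pos2) < (self.chrom1, self.pos1):
            return LigationJunction(
                self.read_id,
                self.chrom2, self.pos2, self.strand2,
                self.chrom1, self.pos1, self.strand1,
                self.sonication_right, self.sonication_left,
            )
        return self


@dataclass
class JunctionTable:
    junctions: list[LigationJunction]
    sample: str = "sample"
    stage_counts: dict = None  # raw / deduplicated / filtered provenance

    def __post_init__(self) -> None:
        if self.stage_counts is None:
            self.stage_counts = {}

    def __len__(self) -> int:
        return len(self.junctions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (j.read_id, j.chrom1, j.pos1, j.chrom2, j.pos2,
                 j.strand1, j.strand2, j.sonication_left, j.sonication_right)
                for j in self.junctions
            ],
            columns=["readID", "chr1", "pos1", "chr2", "pos2", "strand1",
                     "strand2", "sonication_left", "sonication_right"],
        )


def _proximal_end(seg: ReadSegment, side: str) -> int:
    """Genomic coordinate of a segment end.

    ``side='right'``: the end at the segment's read-right boundary (q_end),
    which is g_end on '+' and g_start on '-'.  ``side='left'`` symmetric.
    """
    if side == "right":
        return seg.g_end if seg.strand == "+" else seg.g_start
    return seg.g_start if seg.strand == "+" else seg.g_end


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _oriented_base_from_start(genome, seg: ReadSegment, t: int) -> str | None:
    """Reference base under read position ``t``, anchored at the segment's
    read-left end (valid left of the junction even if the alignment's far
    end is over-extended)."""
    chrom_seq = genome.get(seg.chrom)
    if chrom_seq is None:
        return None
    if seg.strand == "+":
        p = seg.g_start + (t - seg.q_start)
        return chrom_seq[p].upper() if 0 <= p < len(chrom_seq) else None
    p = seg.g_end - 1 - (t - seg.q_start)
    return _COMP[chrom_seq[p].upper()] if 0 <= p < len(chrom_seq) else None


def _oriented_base_from_end(genome, seg: ReadSegment, t: int) -> str | None:
    """Reference base under read position ``t``, anchored at the segment's
    read-right end."""
    chrom_seq = genome.get(seg.chrom)
    if chrom_seq is None:
        return None
    if seg.strand == "+":
        p = seg.g_end - (seg.q_end - t)
        return chrom_seq[p].upper() if 0 <= p < len(chrom_seq) else None
    p = seg.g_start + (seg.q_end - 1 - t)
    return _COMP[chrom_seq[p].upper()] if 0 <= p < len(chrom_seq) else None


def _boundary_coords(prev: ReadSegment, nxt: ReadSegment, s: int) -> tuple[int, int]:
    """Junction coordinates when the read is split at read position ``s``.

    ``prev`` is anchored at its read-left end and ``nxt`` at its read-right
    end, so over-extension of either alignment into the partner fragment
    does not disturb the result.
    """
    if prev.strand == "+":
        pos1 = prev.g_start + (s - prev.q_start)
    else:
        pos1 = prev.g_end - (s - prev.q_start)
    if nxt.strand == "+":
        pos2 = nxt.g_end - (nxt.q_end - s)
    else:
        pos2 = nxt.g_start + (nxt.q_end - s)
    return pos1, pos2


def _refine_split(genome, read_seq: str, prev: ReadSegment,
                  nxt: ReadSegment) -> int:
    """Leftmost consistent split point between two overlapping segments.

    Local alignments routinely extend a few bases past the true ligation
    point wherever the partner fragment's sequence coincidentally matches
    (micro-homology); within that zone every split yields the same read,
    so the junction is reported at the zone's read-left edge — the same
    canonical choice the truth tables of the simulator use.  The walk
    starts at the first segment's read end (guaranteed to lie inside the
    second fragment's territory) and moves left while the read keeps
    matching the second fragment's reference, which is robust to either
    alignment over-extending through chance matches or mismatches.
    """
    s = nxt.q_end
    lo = prev.q_start + 1
    skips = 0
    while s > lo:
        cb = _oriented_base_from_end(genome, nxt, s - 1)
        if cb is None:
            break
        if read_seq[s - 1].upper() == cb:
            s -= 1
            continue
        # tolerate isolated substitutions (sequencing errors): only skip a
        # mismatch when the next 8 bases keep matching, which a junction
        # edge essentially never does by chance
        ctx = range(max(s - 9, lo - 1), s - 1)
        if skips < 3 and len(ctx) == 8 and all(
            (cb2 := _oriented_base_from_end(genome, nxt, t)) is not None
            and read_seq[t].upper() == cb2
            for t in ctx
        ):
            skips += 1
            s -= 1
            continue
        break
    return s


def _verify_left_flank(genome, read_seq, prev: ReadSegment, s: int,
                       n: int = 8) -> bool:
    """Check the read matches the first fragment's reference left of the
    split (at most one mismatch tolerated), guarding against spurious
    splits from multi-mapping or heavily over-extended alignments."""
    mism = 0
    checked = 0
    for t in range(max(prev.q_start, s - n), s):
        ca = _oriented_base_from_start(genome, prev, t)
        if ca is None:
            return False
        checked += 1
        if read_seq[t].upper() != ca:
            mism += 1
    return checked >= 4 and mism <= 1


def call_junctions(
    segments_by_read: dict[str, list[ReadSegment]],
    max_gap: int = MAX_QUERY_GAP,
    genome: dict[str, str] | None = None,
    reads: dict[str, str] | None = None,
    max_overlap_resolve: int = 35,
) -> list[LigationJunction]:
    """Emit one junction per adjacent segment pair of every read.

    Consecutive segments (sorted by read coordinate) whose read-space gap
    is less than ``max_gap`` bp evidence a ligation junction; reads with
    three or more segments yield all consecutive pairs, single-segment
    reads none.  When ``genome`` and ``reads`` (id -> sequence) are
    provided, query overlaps of up to ``max_overlap_resolve`` bp between
    adjacent segments are resolved to the canonical (leftmost) split point
    of the micro-homology zone and both coordinates are reported at that
    split; otherwise only overlaps below ``max_gap`` are accepted, at the
    raw alignment ends.
    The sonication ends are the outer read-space ends of the first and
    last segments of the read.
    """
    out = []
    for read_id, segs in segments_by_read.items():
        if len(segs) < 2:
            continue
        segs = sorted(segs, key=lambda s: s.q_start)
        son_left_read = _proximal_end(segs[0], "left")
        son_right_read = _proximal_end(segs[-1], "right")
        read_seq = reads.get(read_id) if reads is not None else None
        for prev, nxt in zip(segs, segs[1:]):
            overlap = prev.q_end - nxt.q_start
            if -overlap >= max_gap or overlap > max_overlap_resolve:
                continue
            if genome is not None and read_seq is not None:
                s = _refine_split(genome, read_seq, prev, nxt)
                if not (prev.q_start < s < nxt.q_end):
                    continue
                if not _verify_left_flank(genome, read_seq, prev, s):
                    continue
                pos1, pos2 = _boundary_coords(prev, nxt, s)
            else:
                if overlap >= max_gap:
                    continue
                pos1 = _proximal_end(prev, "right")
                pos2 = _proximal_end(nxt, "left")
            j = LigationJunction(
                read_id,
                prev.chrom, pos1, prev.strand,
                nxt.chrom, pos2, nxt.strand,
                son_left_read, son_right_read,
            )
            out.append(j.canonical())
    return out


# ---------------------------------------------------------------------------
# PCR-duplicate removal


def _is_duplicate(a: LigationJunction, b: LigationJunction,
                  wobble: int = WOBBLE) -> bool:
    return (
        a.chrom1 == b.chrom1
        and a.chrom2 == b.chrom2
        and abs(a.pos1 - b.pos1) <= wobble
        and abs(a.pos2 - b.pos2) <= wobble
        and abs(a.sonication_left - b.sonication_left) <= wobble
        and abs(a.sonication_right - b.sonication_right) <= wobble
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def dedup_junctions(
    junctions: Sequence[LigationJunction],
    wobble: int = WOBBLE,
    sample: str = "sample",
) -> JunctionTable:
    """Collapse PCR duplicates under the +/- ``wobble`` bp relation.

    Two junctions are duplicates iff they share both chromosomes and all
    four coordinates (both junction positions and both sonication ends)
    agree within ``wobble`` bp.  Clusters are formed by single linkage and
    the representative with the lexicographically smallest read id is
    kept, which makes the output independent of input order.
    """
    n = len(junctions)
    order = sorted(range(n), key=lambda i: (
        junctions[i].chrom1, junctions[i].pos1))
    uf = _UnionFind(n)
    # sorted sweep: candidates must agree on pos1 within wobble
    for a_pos in range(n):
        i = order[a_pos]
        ji = junctions[i]
        for b_pos in range(a_pos + 1, n):
            k = order[b_pos]
            jk = junctions[k]
            if jk.chrom1 != ji.chrom1 or jk.pos1 - ji.pos1 > wobble:
                break
            if _is_duplicate(ji, jk, wobble):
                uf.union(i, k)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)
    kept = [
        junctions[min(members, key=lambda i: junctions[i].read_id)]
        for members in clusters.values()
    ]
    kept.sort(key=lambda j: (j.chrom1, j.pos1, j.chrom2, j.pos2, j.read_id))
    return JunctionTable(
        kept, sample,
        {"raw": n, "deduplicated": len(kept)},
    )


def dedup_brute_force(
    junctions: Sequence[LigationJunction],
    wobble: int = WOBBLE,
) -> list[LigationJunction]:
    """O(n^2) single-linkage reference used to validate ``dedup_junctions``."""
    n = len(junctions)
    uf = _UnionFind(n)
    for i in range(n):
        for k in range(i + 1, n):
            if _is_duplicate(junctions[i], junctions[k], wobble):
                uf.union(i, k)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)
    kept = [
        junctions[min(members, key=lambda i: junctions[i].read_id)]
        for members in clusters.values()
    ]
    kept.sort(key=lambda j: (j.chrom1, j.pos1, j.chrom2, j.pos2, j.read_id))
    return kept


def filter_junctions(
    table: JunctionTable, min_distance: int = 0
) -> JunctionTable:
    """Drop intra-chromosomal junctions closer than ``min_distance`` bp.

    Inter-chromosomal junctions always pass.  The density-plot export uses
    a 10 bp threshold (self-ligation artefacts cluster near the diagonal);
    matrices use an independently configured threshold, default 0.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    kept = [
        j for j in table.junctions
        if j.chrom1 != j.chrom2 or j.distance >= min_distance
    ]
    counts = dict(table.stage_counts)
    counts["filtered"] = len(kept)
    return JunctionTable(kept, table.sample, counts)


# ---------------------------------------------------------------------------
# pairs-style TSV I/O (1-based on disk, 0-based in memory)


def write_pairs(path: str | Path, table: JunctionTable) -> None:
    with open(path, "w") as fh:
        fh.write("#columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        for j in table.junctions:
            fh.write(
                f"{j.read_id}\t{j.chrom1}\t{j.pos1 + 1}\t{j.chrom2}\t"
                f"{j.pos2 + 1}\t{j.strand1}\t{j.strand2}\t"
                f"{j.sonication_left + 1}\t{j.sonication_right + 1}\n"
            )


def read_pairs(path: str | Path, sample: str = "sample") -> JunctionTable:
    junctions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            junctions.append(
                LigationJunction(
                    f[0], f[1], int(f[2]) - 1, f[5], f[3], int(f[4]) - 1,
                    f[6], int(f[7]) - 1, int(f[8]) - 1,
                )
            )
    return JunctionTable(junctions, sample)
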