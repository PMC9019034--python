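"""Raw FASTQ to located read segments.

Three stages mirror the MCC analysis design: 3' adapter trimming,
FLASH-style overlap merging of read pairs (ligation junctions are
sequenced directly because sonicated inserts are shorter than two read
lengths), and two-pass placement of chimeric reads — a permissive local
alignment against the capture-region sequences splits each read into
segments, and each split segment is then confirmed end-to-end against the
full reference genome.  Junctions are only ever called within a single
(merged or unmerged) read, never across mates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import edlib
from Bio import Align

from .core import TargetRegion
from .io import FastqRecord
from .simulate import revcomp, ADAPTER_R1, ADAPTER_R2

__all__ = [
    "MergedRead",
    "ReadSegment",
    "trim_adapters",
    "merge_pairs",
    "ChimericSplitter",
    "place_segments",
]

SEGMENT_COLUMNS = (
    "read_id", "q_start", "q_end", "chrom", "g_start", "g_end",
    "strand", "score", "identity",
)


@dataclass
class MergedRead:
    id: str
    sequence: str
    quality: str
    merged: bool
    mate_overlap: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSegment:
    """A locally aligned piece of a read, in read and genome space.

    ``q_start``/``q_end`` are 0-based half-open coordinates in the read;
    ``g_start``/``g_end`` the genomic interval it aligns to.  For a '-'
    strand segment the read substring matches the reverse complement of
    the genomic interval, so the read-left end corresponds to ``g_end``.
    """

    read_id: str
    q_start: int
    q_end: int
    chrom: str
    g_start: int
    g_end: int
    strand: str
    score: float
    identity: float
    ambiguous: bool = False

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start


# ---------------------------------------------------------------------------
# adapter trimming


_PROBE_LEN = 12


def _find_adapter(seq: str, adapter: str, max_error: float, min_match: int) -> int:
    """Leftmost position where a 3' adapter match begins, or len(seq).

    A fast exact search for the adapter's first 12 bases handles full
    read-through; shorter adapter prefixes ending at the read's 3' end are
    then checked with the mismatch allowance, longest (leftmost) first.
    """
    n = len(seq)
    probe = adapter[:_PROBE_LEN]
    pos = seq.find(probe)
    if pos != -1:
        return pos
    for ovl in range(min(_PROBE_LEN - 1, n), min_match - 1, -1):
        i = n - ovl
        allowed = int(max_error * ovl)
        mism = 0
        for a, b in zip(seq[i:], adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return i
    return n


def trim_adapters(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    adapter1: str = ADAPTER_R1,
    adapter2: str = ADAPTER_R2,
    max_error: float = 0.1,
    min_match: int = 3,
    min_length: int = 20,
) -> tuple[list[tuple[FastqRecord, FastqRecord]], dict]:
    """Remove 3' adapter read-through; drop pairs trimmed below 20 bp.

    An adapter-matching suffix (up to ``max_error`` mismatch fraction,
    minimum ``min_match`` bp of overlap) is removed from each mate.
    Returns the surviving pairs and a counter dict.
    """
    out = []
    stats = {"pairs_in": 0, "pairs_trimmed": 0, "pairs_dropped_short": 0}
    for r1, r2 in pairs:
        stats["pairs_in"] += 1
        c1 = _find_adapter(r1.sequence, adapter1, max_error, min_match)
        c2 = _find_adapter(r2.sequence, adapter2, max_error, min_match)
        if c1 < len(r1) or c2 < len(r2):
            stats["pairs_trimmed"] += 1
        t1 = FastqRecord(r1.id, r1.sequence[:c1], r1.quality[:c1])
        t2 = FastqRecord(r2.id, r2.sequence[:c2], r2.quality[:c2])
        if len(t1) < min_length or len(t2) < min_length:
            stats["pairs_dropped_short"] += 1
            continue
        out.append((t1, t2))
    return out, stats


# ---------------------------------------------------------------------------
# pair merging


def merge_pairs(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> tuple[list[MergedRead], dict]:
    """FLASH-style overlap merging of mate pairs.

    The 3' end of R1 is compared with the reverse complement of R2 over
    every candidate overlap length; the overlap with the lowest mismatch
    fraction (ties broken towards longer overlaps) wins if it stays below
    ``max_mismatch_density``.  At mismatching positions the consensus
    takes the higher-quality base.  Non-overlapping mates are emitted as
    two unmerged reads tagged with the mate rank.
    """
    out: list[MergedRead] = []
    stats = {"pairs_in": 0, "pairs_merged": 0, "pairs_unmerged": 0}
    for r1, r2 in pairs:
        stats["pairs_in"] += 1
        s2 = revcomp(r2.sequence)
        q2 = r2.quality[::-1]
        merged = _merge_one(r1.sequence, r1.quality, s2, q2,
                            min_overlap, max_mismatch_density)
        if merged is None:
            stats["pairs_unmerged"] += 1
            out.append(MergedRead(f"{r1.id}/1", r1.sequence, r1.quality, False))
            out.append(MergedRead(f"{r2.id}/2", r2.sequence, r2.quality, False))
        else:
            stats["pairs_merged"] += 1
            seq, qual, ovl = merged
            out.append(MergedRead(r1.id, seq, qual, True, ovl))
    return out, stats


def _candidate_overlaps(s1, s2, min_overlap):
    """Plausible overlap lengths between the 3' of s1 and the 5' of s2.

    Exact matches of two 12-bp probes from the start of s2 locate large
    overlaps at C speed; overlaps up to 30 bp are always checked
    exhaustively so that small overlaps survive probe mismatches.
    """
    n1, n2 = len(s1), len(s2)
    cands = set(range(min_overlap, min(min(n1, n2), 30) + 1))
    for probe_off in (0, 12):
        probe = s2[probe_off : probe_off + 12]
        if len(probe) < 12:
            continue
        start = 0
        while True:
            p = s1.find(probe, start)
            if p == -1:
                break
            o = n1 - p + probe_off
            if min_overlap <= o <= min(n1, n2):
                cands.add(o)
            start = p + 1
    return sorted(cands)


def _merge_one(s1, q1, s2, q2, min_overlap, max_density):
    n1, n2 = len(s1), len(s2)
    best = None  # (mismatch_density, overlap)
    for o in _candidate_overlaps(s1, s2, min_overlap):
        allowed = int(max_density * o)
        mism = 0
        ok = True
        for x, y in zip(s1[n1 - o :], s2[:o]):
            if x != y:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if not ok:
            continue
        dens = mism / o
        if best is None or dens < best[0] or (dens == best[0] and o > best[1]):
            best = (dens, o)
    if best is None:
        return None
    o = best[1]
    head = s1[: n1 - o]
    head_q = q1[: n1 - o]
    tail = s2[o:]
    tail_q = q2[o:]
    cons = []
    cons_q = []
    for i in range(o):
        x, xq = s1[n1 - o + i], q1[n1 - o + i]
        y, yq = s2[i], q2[i]
        if x == y or xq >= yq:
            cons.append(x)
            cons_q.append(max(xq, yq))
        else:
            cons.append(y)
            cons_q.append(yq)
    return head + "".join(cons) + tail, head_q + "".join(cons_q) + tail_q, o


# ---------------------------------------------------------------------------
# chimeric splitting against target-region sequences


class ChimericSplitter:
    """Split reads into segments by local alignment to capture regions.

    A k-mer seed index over both strands of every region sequence proposes
    candidate (region, strand, diagonal) windows; each window is then
    scored with a Smith-Waterman local alignment (match +1, mismatch -1,
    gap open -2, gap extend -1).  Segments are selected greedily by score,
    tolerating small read-coordinate overlaps (local alignments extend a
    few bases past a ligation point wherever the partner fragment matches
    by chance); leftover read flanks are re-aligned recursively so both
    sides of a junction are found even when they fall on nearby diagonals.
    """

    def __init__(
        self,
        regions: Sequence[TargetRegion],
        k: int = 15,
        min_score: float = 20.0,
        min_length: int = 20,
        min_identity: float = 0.9,
        max_query_overlap: int = 35,
        open_gap_score: float = -5.0,
        extend_gap_score: float = -3.0,
    ) -> None:
        if not regions:
            raise ValueError("region set must be non-empty")
        self.regions = list(regions)
        self.k = k
        self.min_score = min_score
        self.min_length = min_length
        self.min_identity = min_identity
        self.max_query_overlap = max_query_overlap
        # gap penalties are deliberately stiff: a proximity-ligation read
        # jumps between loci at the junction, and cheap gaps would let a
        # single alignment bridge short genomic jumps (or over-extend past
        # the junction), hiding exactly the short-range contacts the
        # method resolves; 1-2 bp indels inside long segments still align
        self._aligner = Align.PairwiseAligner(
            mode="local",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=open_gap_score,
            extend_gap_score=extend_gap_score,
        )
        # oriented sequences: (region_idx, strand) -> uppercase sequence
        self._oriented: dict[tuple[int, str], str] = {}
        self._index: dict[str, list[tuple[int, str, int]]] = {}
        for ri, region in enumerate(self.regions):
            fwd = region.sequence.upper()
            for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
                self._oriented[(ri, strand)] = seq
                for p in range(len(seq) - k + 1):
                    self._index.setdefault(seq[p : p + k], []).append(
                        (ri, strand, p)
                    )

    # -- seeding -----------------------------------------------------------

    def _candidate_windows(self, seq: str) -> list[tuple[int, str, int, int]]:
        """Propose (region_idx, strand, window_start, window_end) candidates."""
        k = self.k
        hits: dict[tuple[int, str, int], list[tuple[int, int]]] = {}
        for q in range(0, len(seq) - k + 1):
            for (ri, strand, p) in self._index.get(seq[q : q + k], ()):
                diag = (p - q) // 16
                hits.setdefault((ri, strand, diag), []).append((q, p))
        merged: dict[tuple[int, str], list[list[int]]] = {}
        for (ri, strand, _diag), qs in hits.items():
            g_lo = min(p for _, p in qs)
            g_hi = max(p for _, p in qs) + k
            merged.setdefault((ri, strand), []).append([g_lo, g_hi])
        out = []
        pad = 60
        for (ri, strand), spans in merged.items():
            spans.sort()
            fused: list[list[int]] = []
            for lo, hi in spans:
                if fused and lo - pad <= fused[-1][1] + pad:
                    fused[-1][1] = max(fused[-1][1], hi)
                else:
                    fused.append([lo, hi])
            tlen = len(self._oriented[(ri, strand)])
            for lo, hi in fused:
                out.append((ri, strand, max(lo - pad, 0), min(hi + pad, tlen)))
        return out

    # -- alignment ---------------------------------------------------------

    def _best_local(self, query: str, windows) -> tuple | None:
        """Best local alignment of ``query`` over all candidate windows.

        Returns (score, region_idx, strand, query_blocks, target_blocks,
        window_offset) with the gapless aligned blocks preserved, so large
        internal gaps can be re-interpreted as junctions.
        """
        best = None
        for (ri, strand, w_lo, w_hi) in windows:
            target = self._oriented[(ri, strand)][w_lo:w_hi]
            if len(target) < self.min_length:
                continue
            try:
                aln = self._aligner.align(target, query)[0]
            except (IndexError, ValueError):
                continue
            if best is None or aln.score > best[0]:
                tb, qb = aln.aligned
                best = (aln.score, ri, strand, qb.tolist(), tb.tolist(), w_lo)
        return best

    def _gap_split(self, seq, ri, strand, qb, tb, w_lo):
        """Break an alignment at internal gaps >= 5 bp into sub-segments.

        A target-side gap of 5+ bp is a genomic jump the read does not
        carry — exactly what a ligation junction between two nearby
        fragments looks like — and a query-side gap of 5+ bp breaks the
        read-adjacency rule anyway, so both end the current segment.
        Gapless blocks separated by smaller indels stay together.
        """
        wseq = self._oriented[(ri, strand)]
        groups = [[0]]
        for i in range(1, len(qb)):
            qgap = qb[i][0] - qb[i - 1][1]
            tgap = tb[i][0] - tb[i - 1][1]
            if qgap >= 5 or tgap >= 5:
                groups.append([])
            groups[-1].append(i)
        subs = []
        for g in groups:
            q0, q1 = qb[g[0]][0], qb[g[-1]][1]
            t0, t1 = tb[g[0]][0], tb[g[-1]][1]
            matches = 0
            aln_len = 0
            for bi in g:
                a = seq[qb[bi][0] : qb[bi][1]]
                b = wseq[w_lo + tb[bi][0] : w_lo + tb[bi][1]]
                matches += sum(x == y for x, y in zip(a, b))
                aln_len += qb[bi][1] - qb[bi][0]
            ident = matches / max(aln_len, 1)
            score = 2 * matches - aln_len  # +1 match / -1 mismatch
            subs.append(
                (score, ri, strand, int(q0), int(q1),
                 w_lo + int(t0), w_lo + int(t1), ident)
            )
        return subs

    def split(self, read: MergedRead) -> list[ReadSegment]:
        """Maximal local alignments tiling the read, in read order.

        Reads with no acceptable alignment return an empty list (the read
        carries no capture-region sequence and is uninformative).
        """
        seq = read.sequence.upper()
        windows = self._candidate_windows(seq)
        if not windows:
            return []
        raw: list[tuple] = []
        self._cover(seq, 0, len(seq), windows, raw, depth=0)
        # greedy selection by descending score; small query overlaps are
        # tolerated here and resolved to a single split point downstream
        raw.sort(key=lambda t: -t[0])
        chosen: list[tuple] = []
        for cand in raw:
            qs, qe = cand[3], cand[4]
            # a candidate must contribute >= 10 bp of read not already
            # claimed by a higher-scoring segment
            ok = all(
                min(qe, c[4]) - max(qs, c[3])
                <= min(self.max_query_overlap, qe - qs - 10)
                for c in chosen
            )
            if ok:
                chosen.append(cand)
        chosen.sort(key=lambda t: t[3])
        segments = []
        for (score, ri, strand, qs, qe, ts, te, ident) in chosen:
            region = self.regions[ri]
            if strand == "+":
                g_start = region.start + ts
                g_end = region.start + te
            else:
                g_start = region.start + (len(region) - te)
                g_end = region.start + (len(region) - ts)
            segments.append(
                ReadSegment(read.id, qs, qe, region.chrom, g_start, g_end,
                            strand, score, ident)
            )
        return segments

    def _cover(self, seq, lo, hi, windows, out, depth):
        if hi - lo < self.min_length or depth > 6:
            return
        sub = seq[lo:hi]
        best = self._best_local(sub, windows)
        if best is None:
            return
        _, ri, strand, qb, tb, w_lo = best
        subs = self._gap_split(sub, ri, strand, qb, tb, w_lo)
        kept = [
            s for s in subs
            if s[0] >= self.min_score and s[4] - s[3] >= self.min_length
            and s[7] >= self.min_identity
        ]
        if not kept:
            return
        for (score, sri, sstrand, qs, qe, ts, te, ident) in kept:
            out.append((score, sri, sstrand, lo + qs, lo + qe, ts, te, ident))
        first_qs = min(s[3] for s in kept)
        last_qe = max(s[4] for s in kept)
        # recurse on the unclaimed flanks only; a truncated neighbour
        # segment is fine because junction calling re-anchors coordinates
        # on each segment's stable (outer) end
        if first_qs >= self.min_length:
            self._cover(seq, lo, lo + first_qs, windows, out, depth + 1)
        if (hi - lo) - last_qe >= self.min_length:
            self._cover(seq, lo + last_qe, hi, windows, out, depth + 1)


def split_chimeric(
    reads: Iterable[MergedRead],
    regions: Sequence[TargetRegion],
    **kwargs,
) -> tuple[dict[str, list[ReadSegment]], dict]:
    """Split every read; returns {read_id: segments} and stage counts."""
    splitter = ChimericSplitter(regions, **kwargs)
    segments: dict[str, list[ReadSegment]] = {}
    stats = {"reads_in": 0, "reads_on_target": 0, "reads_off_target": 0}
    for read in reads:
        stats["reads_in"] += 1
        segs = splitter.split(read)
        if segs:
            stats["reads_on_target"] += 1
            segments[read.id] = segs
        else:
            stats["reads_off_target"] += 1
    stats["on_target_fraction"] = (
        stats["reads_on_target"] / stats["reads_in"] if stats["reads_in"] else 0.0
    )
    return segments, stats


# ---------------------------------------------------------------------------
# second-pass placement against the full reference


def place_segments(
    segments: dict[str, list[ReadSegment]],
    reads: dict[str, str],
    genome: dict[str, str],
    max_disagreement: int = 1000,
    max_error_fraction: float = 0.25,
) -> tuple[dict[str, list[ReadSegment]], dict]:
    """Confirm each split segment end-to-end against the whole reference.

    The segment's read substring is aligned as an infix of the reference
    (both strands).  A segment whose best placement falls more than
    ``max_disagreement`` bp from the first-pass locus, or which has several
    equally good placements far apart, is flagged ambiguous and excluded
    from junction calling.  Concordant placements refine the genomic
    coordinates.  ``max_error_fraction`` is deliberately permissive: a
    segment may carry a short over-extension past its true ligation point
    (resolved later during junction calling), which inflates its edit
    distance without invalidating the placement.
    """
    chroms = list(genome)
    upper = {c: genome[c].upper() for c in chroms}
    stats = {"segments_in": 0, "segments_placed": 0, "segments_ambiguous": 0}
    out: dict[str, list[ReadSegment]] = {}
    for read_id, segs in segments.items():
        placed = []
        for seg in segs:
            stats["segments_in"] += 1
            query = reads[read_id][seg.q_start : seg.q_end].upper()
            max_ed = int(max_error_fraction * len(query))
            best = None  # (edit_dist, chrom, strand, locations)
            for chrom in chroms:
                for strand in "+-":
                    q = query if strand == "+" else revcomp(query)
                    res = edlib.align(q, upper[chrom], mode="HW",
                                      task="locations", k=max_ed)
                    if res["editDistance"] < 0:
                        continue
                    cand = (res["editDistance"], chrom, strand,
                            res["locations"])
                    if best is None or cand[0] < best[0]:
                        best = cand
                    elif cand[0] == best[0]:
                        best = (best[0], best[1], best[2],
                                list(best[3]) + (cand[3] if chrom == best[1]
                                                 and strand == best[2] else
                                                 [(-10**9, -10**9)]))
            if best is None:
                placed.append(replace(seg, ambiguous=True))
                stats["segments_ambiguous"] += 1
                continue
            ed, chrom, strand, locs = best
            starts = sorted({loc[0] for loc in locs})
            spread = starts[-1] - starts[0] if len(starts) > 1 else 0
            g_start = locs[0][0]
            g_end = locs[0][1] + 1  # edlib end is inclusive
            multi = spread > max_disagreement
            disagree = (
                chrom != seg.chrom
                or strand != seg.strand
                or abs(g_start - seg.g_start) > max_disagreement
            )
            if multi or disagree:
                placed.append(replace(seg, ambiguous=True))
                stats["segments_ambiguous"] += 1
            else:
                ident = 1.0 - ed / max(len(query), 1)
                placed.append(
                    replace(seg, g_start=g_start, g_end=g_end,
                            identity=ident, ambiguous=False)
                )
                stats["segments_placed"] += 1
        kept = [s for s in placed if not s.ambiguous]
        if kept:
            out[read_id] = kept
    return out, stats
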