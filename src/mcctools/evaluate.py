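"""Comparison of pipeline output against simulator ground truth.

Recovery is assessed over the junctions the capture design can in
principle reconstruct: both fragments' junction-proximal ends must lie in
a target region (the chimeric splitter only recognizes capture-region
sequence, exactly as a hybridization panel only enriches it) and the
junction point must be covered by a sequenced read with enough flanking
sequence to align on both sides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BinGrid, TargetRegion, bin_index
from .junctions import JunctionTable
from .matrix import ContactMatrix

__all__ = ["recoverable_truth", "junction_recovery", "anchor_enrichment"]


def recoverable_truth(
    truth: pd.DataFrame, regions: list[TargetRegion]
) -> pd.DataFrame:
    """Non-duplicate truth records whose junction the pipeline can see."""

    def on_target(chrom, pos) -> bool:
        return any(
            r.chrom == chrom and r.interval.contains(int(pos)) for r in regions
        )

    keep = truth[(~truth.is_pcr_duplicate) & truth.junction_in_read]
    mask = [
        on_target(r.chrom1, r.pos1) and on_target(r.chrom2, r.pos2)
        for r in keep.itertuples()
    ]
    return keep[mask]


def junction_recovery(
    truth: pd.DataFrame,
    table: JunctionTable,
    regions: list[TargetRegion],
) -> dict:
    """Fraction of recoverable truth junctions called with exact coordinates.

    Truth and calls are compared as unordered coordinate pairs, both sides
    reported at the canonical (leftmost) edge of the junction's
    micro-homology zone.
    """
    target = recoverable_truth(truth, regions)
    called = {
        (j.chrom1, j.pos1, j.chrom2, j.pos2) for j in table.junctions
    }
    hits = 0
    for r in target.itertuples():
        a = (r.chrom1, int(r.pos1))
        b = (r.chrom2, int(r.pos2))
        lo, hi = sorted([a, b])
        if (lo[0], lo[1], hi[0], hi[1]) in called:
            hits += 1
    n = len(target)
    return {
        "recoverable": n,
        "recovered_exact": hits,
        "recovery_fraction": hits / n if n else float("nan"),
    }


def anchor_enrichment(
    matrix: ContactMatrix,
    anchor: tuple[int, int],
) -> dict:
    """Rank of the anchor bin pair among same-distance off-diagonal bins.

    In a balanced matrix a loop-like anchor should be the strongest entry
    of its distance band (all bin pairs |i - j| equal to the anchor's bin
    separation).  Returns the anchor's value, its band rank (1 = largest),
    and the enrichment over the band median.
    """
    grid = matrix.grid
    m = matrix.balanced if matrix.balanced is not None else matrix.counts
    b1 = bin_index(anchor[0], grid)
    b2 = bin_index(anchor[1], grid)
    lo, hi = min(b1, b2), max(b1, b2)
    d = hi - lo
    if d == 0:
        raise ValueError("anchor pair falls in a single bin")
    band = [
        m[i, i + d]
        for i in range(grid.n_bins - d)
        if not (matrix.mask[i] or matrix.mask[i + d])
    ]
    band = np.asarray(band)
    anchor_val = float(m[lo, hi])
    rank = int((band > anchor_val).sum()) + 1
    med = float(np.median(band))
    return {
        "anchor_value": anchor_val,
        "band_rank": rank,
        "band_size": int(band.size),
        "enrichment_over_band_median": anchor_val / med if med > 0 else float("inf"),
    }
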