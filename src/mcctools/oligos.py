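"""Capture-panel design: dense tiling of target regions with fixed-length
overlapping oligos, plus repeat filtering and a coverage report.

The tiling geometry follows the MCC capture convention: 70-nt oligos with a
35-nt overlap between consecutive tiles, so every interior base is covered
twice when nothing is rejected.  Repeat annotation comes from soft-masking
in the input FASTA (lowercase = repeat); hybridization-capture panels avoid
repetitive probes because they pull down dispersed off-target DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from .core import GenomicInterval, TargetRegion
from . import io as mio

__all__ = [
    "CaptureOligo",
    "PanelDesign",
    "tile_region",
    "filter_repeats",
    "panel_report",
    "write_panel",
]

REJECT_REPEAT = "repeat"
REJECT_HOMOPOLYMER = "homopolymer"
REJECT_N = "N_content"


@dataclass(frozen=True)
class CaptureOligo:
    """One capture tile of a target region."""

    region_name: str
    interval: GenomicInterval
    sequence: str
    repeat_fraction: float
    accepted: bool = True
    rejection_reason: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction outside [0, 1]")


@dataclass
class PanelDesign:
    oligo_len: int = 70
    overlap: int = 35
    repeat_threshold: float = 0.3
    homopolymer_max: int = 10
    oligos: list[CaptureOligo] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.overlap < self.oligo_len:
            raise ValueError("require 0 < overlap < oligo_len")

    @property
    def step(self) -> int:
        return self.oligo_len - self.overlap

    @property
    def accepted(self) -> list[CaptureOligo]:
        return [o for o in self.oligos if o.accepted]


def _make_oligo(region: TargetRegion, offset: int, oligo_len: int) -> CaptureOligo:
    seq = region.sequence[offset : offset + oligo_len]
    repeat_fraction = sum(1 for b in seq if b.islower()) / oligo_len
    iv = GenomicInterval(
        region.chrom, region.start + offset, region.start + offset + oligo_len
    )
    return CaptureOligo(region.name, iv, seq, repeat_fraction)


def tile_region(
    region: TargetRegion,
    oligo_len: int = 70,
    overlap: int = 35,
    repeat_threshold: float = 0.3,
    homopolymer_max: int = 10,
) -> PanelDesign:
    """Tile a region with ``oligo_len``-nt oligos every ``oligo_len - overlap`` bp.

    Candidate starts are region.start + k*step; if the last candidate does
    not reach the region end, one extra right-anchored oligo ending exactly
    at region.end is added so that no tail is left uncovered.  All oligos
    have length ``oligo_len``.
    """
    L = len(region)
    if L < oligo_len:
        raise ValueError(
            f"region {region.name!r} ({L} bp) shorter than oligo length {oligo_len}"
        )
    panel = PanelDesign(oligo_len, overlap, repeat_threshold, homopolymer_max)
    step = panel.step
    n_regular = (L - oligo_len) // step + 1
    offsets = [k * step for k in range(n_regular)]
    if offsets[-1] + oligo_len < L:
        offsets.append(L - oligo_len)
    panel.oligos = [_make_oligo(region, off, oligo_len) for off in offsets]
    return panel


def _longest_homopolymer(seq: str) -> int:
    run = best = 1
    up = seq.upper()
    for a, b in zip(up, up[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def filter_repeats(panel: PanelDesign) -> PanelDesign:
    """Mark oligos failing the repeat / homopolymer / N rules as rejected.

    Rules, in precedence order: any N is a hard rejection; soft-masked
    fraction above ``repeat_threshold`` rejects as repeat; a homopolymer
    run longer than ``homopolymer_max`` rejects.  An empty accepted set is
    a valid (if useless) design, not an error.
    """
    out = []
    for o in panel.oligos:
        reason = None
        if "N" in o.sequence.upper():
            reason = REJECT_N
        elif o.repeat_fraction > panel.repeat_threshold:
            reason = REJECT_REPEAT
        elif _longest_homopolymer(o.sequence) > panel.homopolymer_max:
            reason = REJECT_HOMOPOLYMER
        out.append(
            replace(o, accepted=reason is None, rejection_reason=reason)
        )
    filtered = PanelDesign(
        panel.oligo_len, panel.overlap, panel.repeat_threshold, panel.homopolymer_max
    )
    filtered.oligos = out
    return filtered


def panel_report(
    panel: PanelDesign, regions: list[TargetRegion]
) -> dict[str, dict]:
    """Per-region coverage summary over the accepted oligo set.

    Reports oligo counts, bases covered at least once and at least twice,
    and the largest uncovered gap (rejections leave holes in the tiling).
    """
    by_region: dict[str, list[CaptureOligo]] = {r.name: [] for r in regions}
    for o in panel.accepted:
        if o.region_name in by_region:
            by_region[o.region_name].append(o)
    report = {}
    for region in regions:
        L = len(region)
        depth = [0] * L
        for o in by_region[region.name]:
            for p in range(o.interval.start - region.start, o.interval.end - region.start):
                depth[p] += 1
        covered1 = sum(1 for d in depth if d >= 1)
        covered2 = sum(1 for d in depth if d >= 2)
        # largest run of zero-depth positions
        gap = best_gap = 0
        for d in depth:
            gap = gap + 1 if d == 0 else 0
            best_gap = max(best_gap, gap)
        n_total = sum(1 for o in panel.oligos if o.region_name == region.name)
        report[region.name] = {
            "region_length": L,
            "n_oligos": n_total,
            "n_accepted": len(by_region[region.name]),
            "bases_covered_1x": covered1,
            "bases_covered_2x": covered2,
            "fraction_covered": covered1 / L,
            "largest_gap": best_gap,
        }
    return report


def write_panel(panel: PanelDesign, out_prefix: str | Path) -> None:
    """Write oligo FASTA (names encode coordinates) and a status BED."""
    out_prefix = Path(out_prefix)
    fasta = {
        f"{o.interval.chrom}:{o.interval.start}-{o.interval.end}": o.sequence
        for o in panel.oligos
    }
    mio.write_fasta(out_prefix.with_suffix(".fa"), fasta)
    mio.write_bed(
        out_prefix.with_suffix(".bed"),
        (
            (
                o.interval,
                [
                    o.region_name,
                    "accepted" if o.accepted else f"rejected:{o.rejection_reason}",
                ],
            )
            for o in panel.oligos
        ),
    )
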