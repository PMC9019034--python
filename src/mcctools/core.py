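"""Coordinate conventions, interval types, and binning arithmetic.

All internal coordinates are 0-based, half-open ``[start, end)``, matching
BED.  Any 1-based external table (e.g. the pairs-style junction TSV) is
converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "TargetRegion",
    "BinGrid",
    "bin_index",
    "expected_fragment_length",
]

_DNA_ALPHABET = frozenset("ACGTNacgtn")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TargetRegion:
    """A named genomic interval enriched by the capture panel.

    ``sequence`` carries soft-masking: lowercase bases mark repeats, as in
    a RepeatMasker-processed FASTA.  Its length must equal the interval
    length so that region-relative offsets map 1:1 onto genome positions.
    """

    name: str
    interval: GenomicInterval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"region {self.name!r}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self.interval)}"
            )
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"region {self.name!r}: non-DNA characters {sorted(bad)!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width binning of a target region.

    The last bin may be short when the region length is not divisible by
    ``binsize``; it is a full-status bin like any other.
    """

    region: TargetRegion
    binsize: int
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")
        object.__setattr__(
            self, "n_bins", math.ceil(len(self.region) / self.binsize)
        )

    def bin_start(self, b: int) -> int:
        """Genomic start coordinate of bin ``b``."""
        if not 0 <= b < self.n_bins:
            raise IndexError(f"bin {b} outside grid of {self.n_bins} bins")
        return self.region.start + b * self.binsize


def bin_index(pos: int, grid: BinGrid) -> int:
    """Map a genomic position to its bin ordinal on ``grid``.

    Raises ``ValueError`` for positions outside the grid's region; every
    in-region position maps to exactly one of ``0..n_bins-1``.
    """
    region = grid.region
    if not region.interval.contains(pos):
        raise ValueError(
            f"position {pos} outside region {region.interval}"
        )
    return (pos - region.start) // grid.binsize


def expected_fragment_length(motif_len: int) -> int:
    """Expected restriction-fragment length for a ``motif_len``-bp cutter.

    Under uniform i.i.d. base composition a recognition motif of length k
    occurs every 4**k bp on average, so fragment-based 3C methods cannot
    resolve contacts below that scale: a 4-cutter (e.g. DpnII) is bounded
    at 256 bp and a 6-cutter (e.g. HindIII) at 4096 bp.  MNase digestion is
    largely sequence-independent, which is what removes this resolution
    bound for MCC-style libraries.
    """
    if motif_len < 0:
        raise ValueError("motif_len must be >= 0")
    return 4**motif_len
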