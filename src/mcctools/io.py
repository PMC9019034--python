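"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA (soft-masked, via Biopython), BED3+ region files, FASTQ (optionally
gzipped), and the pairs-style junction TSV.  Junction positions are 0-based
internally and converted to 1-based on output, matching pairs-format
consumers; the conversion happens here and nowhere else.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, TargetRegion

__all__ = [
    "FastqRecord",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "load_regions",
    "read_fastq",
    "write_fastq",
    "PAIRS_COLUMNS",
]

PAIRS_COLUMNS = (
    "readID",
    "chr1",
    "pos1",
    "chr2",
    "pos2",
    "strand1",
    "strand2",
    "sonication_left",
    "sonication_right",
)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / BED


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence}, preserving soft-masking."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read a BED3+ file as [(name, interval)].

    Column 4 provides the name when present; otherwise a ``chrom:start-end``
    label is synthesized.  Coordinates are BED-native (0-based half-open),
    which is also the internal convention.
    """
    out: list[tuple[str, GenomicInterval]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            iv = GenomicInterval(chrom, start, end)
            name = fields[3] if len(fields) >= 4 else str(iv)
            out.append((name, iv))
    return out


def write_bed(
    path: str | Path,
    entries: Iterable[tuple[GenomicInterval, Sequence[str]]],
) -> None:
    """Write BED lines; each entry is (interval, extra-columns)."""
    with _open_text(path, "wt") as fh:
        for iv, extra in entries:
            cols = [iv.chrom, str(iv.start), str(iv.end), *extra]
            fh.write("\t".join(cols) + "\n")


def load_regions(
    fasta_path: str | Path, bed_path: str | Path
) -> list[TargetRegion]:
    """Combine a soft-masked genome FASTA and a BED of target intervals."""
    genome = read_fasta(fasta_path)
    regions = []
    for name, iv in read_bed(bed_path):
        if iv.chrom not in genome:
            raise ValueError(f"region {name!r}: chromosome {iv.chrom!r} not in FASTA")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"region {name!r}: interval {iv} exceeds chromosome length "
                f"{len(chrom_seq)}"
            )
        regions.append(TargetRegion(name, iv, chrom_seq[iv.start : iv.end]))
    return regions


# ---------------------------------------------------------------------------
# FASTQ


@dataclass
class FastqRecord:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"record {self.id!r}: sequence and quality lengths differ"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream FASTQ records; malformed records raise with the record number."""
    with _open_text(path) as fh:
        recno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            recno += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"{path}: malformed FASTQ record {recno}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {recno}: sequence/quality length mismatch"
                )
            yield FastqRecord(header[1:].split()[0], seq, qual)


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
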