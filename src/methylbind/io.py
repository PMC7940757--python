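"""Readers and writers for the external file formats the pipeline touches.

All genomic coordinates are 0-based half-open after parsing, matching the
BED convention; interval length is always ``end - start``.  Chromosome
names are matched by exact string comparison — no ``chr`` prefix
normalisation is ever applied, so a mismatch between inputs surfaces as an
empty (logged) query instead of silently renamed data.

Supported formats
-----------------
* FASTA genome sequence (via Bio.SeqIO), case-folded to uppercase.
* Per-cytosine methylation BED in a count dialect (Bismark
  methylation-extractor style).  Two column layouts are accepted, selected
  by ``dialect``: ``meth_total`` (columns 5–6 are methylated reads and
  total reads) and ``meth_unmeth`` (columns 5–6 are methylated and
  unmethylated read counts, summed on read).  Percentage-only files are
  rejected because replicate merging sums read counts.
* ENCODE narrowPeak (BED6+4).
* chromHMM-style labeled BED segmentations.
* Plain BED6 gene annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: chromosome name -> uppercase sequence over {A, C, G, T, N}
GenomeSequence = Dict[str, str]

PathLike = Union[str, Path]


@dataclass(frozen=True, slots=True)
class CytosineRecord:
    """One cytosine locus from a bisulfite methylation call file."""

    chrom: str
    pos: int  # 0-based
    strand: str  # '+' or '-'
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.meth_reads <= self.total_reads):
            raise ValueError(
                f"meth_reads {self.meth_reads} out of range for "
                f"total_reads {self.total_reads} at {self.chrom}:{self.pos}"
            )


@dataclass(slots=True)
class Peak:
    """A narrowPeak interval (0-based half-open) with optional summit offset."""

    chrom: str
    start: int
    end: int
    name: str = "."
    signal: float = 0.0
    summit: Optional[int] = None  # offset from start; None = unknown
    dataset_id: str = ""
    tf: str = ""
    cell: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty peak interval {self.chrom}:{self.start}-{self.end}")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError(f"summit offset {self.summit} outside peak {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Summit position if known, else the interval midpoint."""
        if self.summit is not None:
            return self.start + self.summit
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class SegmentInterval:
    """A labeled chromatin-state interval; labels are kept verbatim."""

    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True, slots=True)
class GeneInterval:
    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."


METH_DIALECTS = ("meth_total", "meth_unmeth")


def read_methylation_bed(path: PathLike, dialect: str = "meth_total") -> List[CytosineRecord]:
    """Read a count-dialect methylation BED into :class:`CytosineRecord` list.

    Expected columns: chrom, start, end, strand, then two count columns
    whose meaning depends on *dialect*.  Input order is preserved.
    """
    if dialect not in METH_DIALECTS:
        raise ValueError(f"unknown methylation dialect {dialect!r}; choose from {METH_DIALECTS}")
    records: List[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 tab-separated columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                strand = fields[3]
                a = int(fields[4])
                b = int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from None
            meth, total = (a, b) if dialect == "meth_total" else (a, a + b)
            if meth > total:
                raise ValueError(f"{path}:{lineno}: methylated reads {meth} exceed total {total}")
            try:
                records.append(CytosineRecord(chrom, start, strand, meth, total))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_methylation_bed(records: Sequence[CytosineRecord], path: PathLike) -> None:
    """Write records in the ``meth_total`` dialect."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.strand}\t{r.meth_reads}\t{r.total_reads}\n")


def read_narrowpeak(path: PathLike, tf: str = "", cell: str = "", dataset_id: str = "") -> List[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Column 10 is the summit offset from the peak start; ``-1`` means
    unknown and maps to ``summit=None`` (downstream falls back to the
    interval midpoint).
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                signal = float(fields[6])
                summit = int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            peaks.append(
                Peak(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3],
                    signal=signal,
                    summit=None if summit < 0 else summit,
                    dataset_id=dataset_id,
                    tf=tf,
                    cell=cell,
                )
            )
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = -1 if p.summit is None else p.summit
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t{p.signal}\t-1\t-1\t{summit}\n"
            )


def read_segmentation(path: PathLike) -> List[SegmentInterval]:
    """Read a chromHMM-style labeled BED (>=4 columns, column 4 = state label).

    Intervals are returned verbatim: they may overlap or leave gaps and are
    never merged.
    """
    segments: List[SegmentInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: labeled BED needs >=4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            segments.append(SegmentInterval(fields[0], start, end, fields[3]))
    return segments


def write_segmentation(segments: Sequence[SegmentInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.label}\n")


def read_bed6_genes(path: PathLike) -> List[GeneInterval]:
    """Read a BED6 gene annotation (name in column 4, strand in column 6)."""
    genes: List[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: gene BED needs >=4 columns")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = fields[5] if len(fields) >= 6 else "."
            genes.append(GeneInterval(fields[0], start, end, fields[3], strand))
    return genes


def write_bed6_genes(genes: Sequence[GeneInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def read_fasta(path: PathLike) -> GenomeSequence:
    """Read a (multi-)FASTA into a chromosome -> uppercase sequence mapping."""
    genome: GenomeSequence = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: GenomeSequence, path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
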