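"""A queryable per-CpG methylome built from bisulfite cytosine records.

The methylation level of a locus is the ratio of methylated reads to total
reads covering it; replicate experiments are merged by summing read counts
per locus before any ratio is taken.  By default the two symmetric
cytosines of a CpG dinucleotide are merged into one "CpG unit" anchored at
the + strand C (symmetric CpG methylation), because the downstream
statistics reason about CpG sites rather than strand-specific cytosines.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import CytosineRecord, GenomeSequence

logger = logging.getLogger(__name__)


def methylation_level(meth_reads: int, total_reads: int) -> float:
    """meth/total, or NaN when the locus has no coverage."""
    if meth_reads > total_reads:
        raise ValueError(f"meth_reads {meth_reads} > total_reads {total_reads}")
    if total_reads == 0:
        return float("nan")
    return meth_reads / total_reads


def merge_replicates(
    rep_a: Sequence[CytosineRecord], rep_b: Sequence[CytosineRecord]
) -> List[CytosineRecord]:
    """Merge two replicate call sets by summing read counts per locus.

    Loci covered by only one replicate pass through unchanged.  The result
    is sorted by (chrom, pos, strand); the operation is commutative and
    associative over replicate sets.
    """
    counts: Dict[Tuple[str, int, str], List[int]] = {}
    for rep in (rep_a, rep_b):
        seen = set()
        for r in rep:
            key = (r.chrom, r.pos, r.strand)
            if key in seen:
                raise ValueError(f"duplicate locus within one replicate: {key}")
            seen.add(key)
            if key in counts and rep is rep_b:
                counts[key][0] += r.meth_reads
                counts[key][1] += r.total_reads
            elif key in counts:  # duplicate inside rep_a already caught by seen
                raise ValueError(f"duplicate locus within one replicate: {key}")
            else:
                counts[key] = [r.meth_reads, r.total_reads]
    return [
        CytosineRecord(chrom, pos, strand, m, t)
        for (chrom, pos, strand), (m, t) in sorted(counts.items())
    ]


@dataclass
class MethylomeTrack:
    """Sorted per-chromosome CpG units with read counts and derived levels.

    ``levels`` is NaN wherever ``total < min_coverage``; such units are
    excluded from every level statistic and from interval queries.
    """

    positions: Dict[str, np.ndarray]  # strictly increasing int64 per chrom
    meth: Dict[str, np.ndarray]
    total: Dict[str, np.ndarray]
    cpg_unit: bool = True
    min_coverage: int = 1
    levels: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.levels:
            for chrom, tot in self.total.items():
                with np.errstate(invalid="ignore", divide="ignore"):
                    lv = self.meth[chrom] / tot
                lv = np.where(tot >= max(self.min_coverage, 1), lv, np.nan)
                self.levels[chrom] = lv
        for chrom, pos in self.positions.items():
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def chroms(self) -> List[str]:
        return list(self.positions)

    @property
    def n_units(self) -> int:
        return sum(len(p) for p in self.positions.values())

    #: span of one unit on the genome (2 bp for a merged CpG dinucleotide)
    @property
    def unit_span(self) -> int:
        return 2 if self.cpg_unit else 1

    def query_interval(self, chrom: str, start: int, end: int) -> Tuple[np.ndarray, np.ndarray]:
        """Positions and levels of covered units with ``start <= pos < end``.

        Units without defined levels (coverage below ``min_coverage``) are
        omitted.  Unknown chromosomes yield an empty (logged) result.
        Binary search keeps the query sublinear in track size.
        """
        if start >= end:
            raise ValueError(f"empty query interval [{start}, {end})")
        if chrom not in self.positions:
            logger.debug("query on unknown chromosome %r", chrom)
            return np.empty(0, dtype=np.int64), np.empty(0)
        pos = self.positions[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        p = pos[lo:hi]
        lv = self.levels[chrom][lo:hi]
        defined = ~np.isnan(lv)
        return p[defined], lv[defined]


def build_track(
    records: Iterable[CytosineRecord],
    merge_cpg_strands: bool = True,
    genome: Optional[GenomeSequence] = None,
    min_coverage: int = 1,
    drop_non_cpg: bool = True,
) -> MethylomeTrack:
    """Assemble a :class:`MethylomeTrack` from per-cytosine records.

    With ``merge_cpg_strands`` (the default) a + strand C at position ``p``
    and the − strand C at ``p+1`` of the same CpG dinucleotide become a
    single unit at ``p`` with summed counts; the genome is required to
    verify CpG context.  Records outside CpG context (CHG/CHH) are dropped
    with a logged count by default, or kept unmerged with a warning when
    ``drop_non_cpg`` is false.
    """
    if merge_cpg_strands and genome is None:
        raise ValueError("merge_cpg_strands requires a genome to verify CpG context")

    by_chrom: Dict[str, List[CytosineRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)

    positions: Dict[str, np.ndarray] = {}
    meth: Dict[str, np.ndarray] = {}
    total: Dict[str, np.ndarray] = {}
    n_non_cpg = 0

    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        pos = np.array([r.pos for r in recs], dtype=np.int64)
        m = np.array([r.meth_reads for r in recs], dtype=np.int64)
        t = np.array([r.total_reads for r in recs], dtype=np.int64)

        if merge_cpg_strands:
            seq = genome.get(chrom, "") if genome else ""
            nseq = len(seq)
            strands = np.array([r.strand == "+" for r in recs])
            unit = np.full(len(recs), -1, dtype=np.int64)
            # + strand C at p with genome CG at p -> unit p
            # - strand C at p (genomic G) with genome CG at p-1 -> unit p-1
            for i in range(len(recs)):
                p = int(pos[i])
                if strands[i]:
                    if p + 1 < nseq and seq[p] == "C" and seq[p + 1] == "G":
                        unit[i] = p
                else:
                    if 1 <= p < nseq and seq[p - 1] == "C" and seq[p] == "G":
                        unit[i] = p - 1
            in_cpg = unit >= 0
            n_non_cpg += int((~in_cpg).sum())
            if drop_non_cpg:
                unit, m, t = unit[in_cpg], m[in_cpg], t[in_cpg]
            else:
                if (~in_cpg).any():
                    logger.warning(
                        "%d non-CpG records on %s kept unmerged", int((~in_cpg).sum()), chrom
                    )
                unit = np.where(in_cpg, unit, pos)
            if len(unit) == 0:
                continue
            upos, inv = np.unique(unit, return_inverse=True)
            um = np.zeros(len(upos), dtype=np.int64)
            ut = np.zeros(len(upos), dtype=np.int64)
            np.add.at(um, inv, m)
            np.add.at(ut, inv, t)
            positions[chrom], meth[chrom], total[chrom] = upos, um, ut
        else:
            order = np.argsort(pos, kind="stable")
            pos, m, t = pos[order], m[order], t[order]
            upos, inv = np.unique(pos, return_inverse=True)
            if len(upos) != len(pos):
                raise ValueError(f"duplicate per-strand positions on {chrom}")
            positions[chrom], meth[chrom], total[chrom] = pos, m, t

    if merge_cpg_strands and n_non_cpg and drop_non_cpg:
        logger.info("dropped %d non-CpG cytosine records", n_non_cpg)

    return MethylomeTrack(
        positions=positions,
        meth=meth,
        total=total,
        cpg_unit=merge_cpg_strands,
        min_coverage=min_coverage,
    )
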