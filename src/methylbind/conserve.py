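"""Cross-cell-type conservation of reference-cell binding regions.

For each reference peak, occupancy k counts the surveyed cell types —
including the reference itself — whose peak set overlaps it by at least
one base (half-open intervals, so abutting peaks do not overlap).  A peak
is conserved when k/N strictly exceeds the occupancy threshold (default
0.8: with six cells, 5/6 ≈ 0.833 is conserved, 4/6 is not).  Conserved
fractions are reported separately for hi- and low-methylation reference
peaks.  Nearby genes of a region set are those overlapping any region
extended by ±1000 bp (clipped at the chromosome start).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .io import GeneInterval, Peak
from .peaks import PipelineThresholds


class PeakSetIndex:
    """Interval trees over one cell type's peak set."""

    def __init__(self, peaks: Iterable[Peak]):
        self._trees: Dict[str, IntervalTree] = {}
        for p in peaks:
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def occupancy(ref_peak: Peak, cell_peak_sets: Sequence[PeakSetIndex | Sequence[Peak]]) -> int:
    """Number of surveyed peak sets overlapping the reference peak by >=1 bp,
    plus one for the reference cell itself."""
    k = 1
    for cell in cell_peak_sets:
        index = cell if isinstance(cell, PeakSetIndex) else PeakSetIndex(cell)
        if index.overlaps(ref_peak.chrom, ref_peak.start, ref_peak.end):
            k += 1
    return k


@dataclass
class ConservationRecord:
    peak: Peak
    mean_methylation: float
    occupancy: int  # k, reference included
    n_cells: int  # N, reference included
    conserved: bool

    @property
    def occupancy_fraction(self) -> float:
        return self.occupancy / self.n_cells


def conservation_records(
    ref_peaks: Sequence[Peak],
    ref_mean_levels: Sequence[float],
    other_cell_sets: Sequence[Sequence[Peak]],
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> List[ConservationRecord]:
    """Occupancy and conserved flag for every reference peak.

    ``other_cell_sets`` excludes the reference cell; N = len(others) + 1.
    """
    if len(ref_peaks) != len(ref_mean_levels):
        raise ValueError("one mean level per reference peak required")
    indexes = [PeakSetIndex(cell) for cell in other_cell_sets]
    n_cells = len(indexes) + 1
    records = []
    for peak, level in zip(ref_peaks, ref_mean_levels):
        k = occupancy(peak, indexes)
        records.append(
            ConservationRecord(
                peak=peak,
                mean_methylation=level,
                occupancy=k,
                n_cells=n_cells,
                conserved=k / n_cells > thresholds.conserved_occupancy,
            )
        )
    return records


def conserved_fraction_by_group(
    records: Sequence[ConservationRecord], groups: Sequence[str]
) -> Dict[str, float]:
    """Fraction of conserved peaks per methylation group ('hi'/'low').

    ``groups`` carries the peaks-module classification, aligned with
    ``records``; every group present must be non-empty by construction.
    """
    if len(records) != len(groups):
        raise ValueError("one group per record required")
    totals: Dict[str, int] = {}
    hits: Dict[str, int] = {}
    for rec, group in zip(records, groups):
        totals[group] = totals.get(group, 0) + 1
        hits[group] = hits.get(group, 0) + int(rec.conserved)
    if not totals:
        raise ValueError("no conservation records")
    return {g: hits[g] / totals[g] for g in sorted(totals)}


def genes_near_regions(
    regions: Sequence[Tuple[str, int, int]],
    genes: Sequence[GeneInterval],
    window: int = 1000,
) -> Set[str]:
    """Names of genes overlapping any region extended by ±window bp.

    Extension is clipped at the chromosome start; results are deduplicated.
    """
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.name)
    names: Set[str] = set()
    for chrom, start, end in regions:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(max(start - window, 0), end + window):
            names.add(iv.data)
    return names
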