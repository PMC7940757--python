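"""Chromatin-state annotation of peaks and DHS methylation summaries.

Each peak is assigned the single segmentation label with the largest total
base-pair overlap (majority rule; ties break lexicographically).  Peaks
overlapped by no segment are labeled ``Unannotated`` with overlap fraction
1.0 — the whole peak is unannotated.  Label strings are kept verbatim;
mapping chromHMM mnemonics onto coarse classes is the caller's business
via a two-column label->class file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
from intervaltree import IntervalTree

from .io import Peak, SegmentInterval
from .methylome import MethylomeTrack
from .peaks import PeakMethylation, PipelineThresholds, himethyl_fraction, peak_mean_methylation

UNANNOTATED = "Unannotated"


@dataclass
class StateAssignment:
    peak: Peak
    label: str
    overlap_fraction: float  # in (0, 1]


class SegmentationIndex:
    """Interval-tree index over a labeled segmentation, per chromosome."""

    def __init__(self, segments: Iterable[SegmentInterval]):
        self._trees: Dict[str, IntervalTree] = {}
        for seg in segments:
            self._trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end, seg.label)

    def overlapping(self, chrom: str, start: int, end: int) -> List[SegmentInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [SegmentInterval(chrom, iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end)]


def assign_chromatin_state(
    peak: Peak, segmentation: Union[SegmentationIndex, Iterable[SegmentInterval]]
) -> StateAssignment:
    """Label with the maximum total overlap with the peak.

    Splitting a segment into adjacent same-label pieces never changes the
    assignment, because overlaps are summed per label.
    """
    index = segmentation if isinstance(segmentation, SegmentationIndex) else SegmentationIndex(segmentation)
    overlap: Dict[str, int] = {}
    for seg in index.overlapping(peak.chrom, peak.start, peak.end):
        bp = min(seg.end, peak.end) - max(seg.start, peak.start)
        if bp > 0:
            overlap[seg.label] = overlap.get(seg.label, 0) + bp
    if not overlap:
        return StateAssignment(peak, UNANNOTATED, 1.0)
    best = min(overlap.items(), key=lambda kv: (-kv[1], kv[0]))
    return StateAssignment(peak, best[0], best[1] / peak.length)


def state_composition(
    assignments_by_group: Mapping[str, Sequence[StateAssignment]],
    label_map: Mapping[str, str] | None = None,
) -> Dict[str, Dict[str, float]]:
    """Per-group label fractions (summing to 1 within each group).

    An optional label->class mapping coarsens labels before counting;
    unmapped labels pass through verbatim.
    """
    out: Dict[str, Dict[str, float]] = {}
    for group, assignments in assignments_by_group.items():
        if not assignments:
            raise ValueError(f"empty assignment group {group!r}")
        counts: Dict[str, int] = {}
        for a in assignments:
            label = label_map.get(a.label, a.label) if label_map else a.label
            counts[label] = counts.get(label, 0) + 1
        n = len(assignments)
        out[group] = {label: c / n for label, c in sorted(counts.items())}
    return out


def read_label_map(path: Union[str, Path]) -> Dict[str, str]:
    """Read a two-column (label TAB class) mapping file."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'label<TAB>class'")
            mapping[fields[0]] = fields[1]
    return mapping


def dhs_methylated_fraction(
    dhs_peaks: Sequence[Peak],
    track: MethylomeTrack,
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> float:
    """Fraction of DHS intervals whose mean CpG methylation is hi (> 0.6).

    Identical machinery to peak classification: CpG-free DHSs are excluded,
    and an all-CpG-free input is an error.
    """
    meths = [peak_mean_methylation(p, track, thresholds) for p in dhs_peaks]
    return himethyl_fraction(meths)
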