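"""Dataset-level filtering and per-peak methylation statistics.

A peak's methylation level is the unweighted mean methylation of the CpG
units inside it.  Peaks whose mean exceeds the hi threshold (default 0.6,
strict ``>``) are "hi-methyl"; peaks containing no covered CpG are
unassigned and excluded from fractions, because a methylation statement
about a CpG-free interval is vacuous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import Peak
from .methylome import MethylomeTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineThresholds:
    """The pipeline's classification constants, all configurable.

    hi_peak_threshold : peaks with mean CpG methylation strictly above this
        are hi-methyl.
    site_high / site_low : binding-site grouping cutoffs; a site is high
        when its level is strictly above ``site_high``, low when strictly
        below ``site_low``, middle otherwise.
    min_peak_count : datasets with fewer peaks are discarded.
    conserved_occupancy : a reference peak is conserved when its occupancy
        fraction across surveyed cell types is strictly above this.
    flank_bp : half-width of the methylation metaplot window around a
        binding-site center.
    gene_window_bp : extension applied to regions when collecting nearby
        genes.
    """

    hi_peak_threshold: float = 0.6
    site_high: float = 0.6
    site_low: float = 0.2
    min_peak_count: int = 500
    conserved_occupancy: float = 0.8
    flank_bp: int = 1600
    gene_window_bp: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.site_low < self.site_high <= 1.0):
            raise ValueError("require 0 <= site_low < site_high <= 1")
        if not (0.0 <= self.hi_peak_threshold <= 1.0):
            raise ValueError("hi_peak_threshold must lie in [0, 1]")


@dataclass
class PeakMethylation:
    """Per-peak methylation summary."""

    peak: Peak
    n_cpgs: int
    mean_level: float  # NaN when no covered CpG lies in the peak
    group: str  # 'hi', 'low' or 'unassigned'

    @property
    def assigned(self) -> bool:
        return self.group != "unassigned"


Dataset = Tuple[str, str, str, List[Peak]]  # (tf, cell, dataset_id, peaks)


def filter_datasets(
    datasets: Sequence[Dataset], thresholds: PipelineThresholds = PipelineThresholds()
) -> List[Dataset]:
    """Drop datasets below the minimum peak count, then keep a single
    dataset per (TF, cell): the one with the most peaks (ties broken by the
    lexicographically smallest dataset id, logged)."""
    big = [d for d in datasets if len(d[3]) >= thresholds.min_peak_count]
    best: Dict[Tuple[str, str], Dataset] = {}
    for d in big:
        key = (d[0], d[1])
        cur = best.get(key)
        if cur is None or len(d[3]) > len(cur[3]):
            best[key] = d
        elif len(d[3]) == len(cur[3]):
            winner = min(cur, d, key=lambda x: x[2])
            logger.info(
                "peak-count tie for %s/%s between %s and %s; keeping %s",
                key[0], key[1], cur[2], d[2], winner[2],
            )
            best[key] = winner
    return list(best.values())


def peak_mean_methylation(
    peak: Peak, track: MethylomeTrack, thresholds: PipelineThresholds = PipelineThresholds()
) -> PeakMethylation:
    """Mean of the defined CpG levels inside ``[start, end)``.

    Returns an unassigned record (NaN mean) when the peak contains no
    covered CpG.
    """
    _, levels = track.query_interval(peak.chrom, peak.start, peak.end)
    if len(levels) == 0:
        return PeakMethylation(peak, 0, float("nan"), "unassigned")
    mean = float(np.mean(levels))
    return PeakMethylation(peak, len(levels), mean, classify_peak(mean, thresholds))


def classify_peak(
    mean_level: float, thresholds: PipelineThresholds = PipelineThresholds()
) -> str:
    """'hi' iff the mean level is strictly above the hi threshold."""
    if math.isnan(mean_level):
        raise ValueError("cannot classify an undefined methylation level")
    return "hi" if mean_level > thresholds.hi_peak_threshold else "low"


def himethyl_fraction(peak_meths: Iterable[PeakMethylation]) -> float:
    """Fraction of assigned peaks classified hi; unassigned peaks are
    excluded from numerator and denominator."""
    assigned = [p for p in peak_meths if p.assigned]
    if not assigned:
        raise ValueError("no peaks with assigned methylation")
    return sum(p.group == "hi" for p in assigned) / len(assigned)


def methylation_distribution(
    peak_meths: Iterable[PeakMethylation], bin_width: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram (edges, counts) of assigned peak mean levels over [0, 1].

    Counts sum to the number of assigned peaks; the last bin is closed at 1.
    """
    levels = np.array([p.mean_level for p in peak_meths if p.assigned])
    if len(levels) == 0:
        raise ValueError("no peaks with assigned methylation")
    n_bins = int(math.ceil(1.0 / bin_width - 1e-12))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(levels, bins=edges)
    return edges, counts
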