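"""Binding-site relocation and methylation-aware motif reconstruction.

Each peak is scanned with the PWM of its methylation group and the single
best placement is taken as the binding site.  A site's methylation level is
the *maximum* defined CpG-unit level overlapping the site (a site may span
several CpGs); sites are grouped high / middle / low by strict thresholds
(default > 0.6 high, < 0.2 low), or ``no_cpg`` when no CpG overlaps.

The methylation-aware motif re-reads each located site on its binding
strand and records a cytosine in CpG context as E when the CpG unit's
methylation exceeds ``e_threshold``; all other bases are recorded verbatim
over the extended alphabet {A, C, G, T, E}.  Collapsing E back onto C
reproduces the plain base counts of the same sites exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import GenomeSequence, Peak
from .methylome import MethylomeTrack
from .motif import Pwm, reverse_complement, scan_peak
from .peaks import PipelineThresholds

logger = logging.getLogger(__name__)

EXTENDED_ALPHABET = "ACGTE"


@dataclass
class BindingSite:
    """A relocated binding site inside a peak."""

    peak: Peak
    start: int  # genomic start of the site (forward strand)
    strand: str
    score: float
    sequence: str  # forward-strand genomic sequence of length L
    site_methylation: float = float("nan")  # NaN = no CpG overlaps
    methyl_group: str = "no_cpg"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def center(self) -> int:
        return self.start + self.length // 2

    @property
    def reading_sequence(self) -> str:
        """Site sequence 5'->3' on the binding strand."""
        return self.sequence if self.strand == "+" else reverse_complement(self.sequence)


@dataclass
class MethylMotif:
    """Count matrix over {A, C, G, T, E}; E is a methylated CpG cytosine."""

    counts: np.ndarray  # (L, 5) non-negative ints
    n_sites: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 5:
            raise ValueError("MethylMotif counts must be (L, 5)")
        if self.n_sites and not np.all(self.counts.sum(axis=1) == self.n_sites):
            raise ValueError("every column must sum to n_sites")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def collapse_to_acgt(self) -> np.ndarray:
        """(L, 4) plain base counts with E folded back onto C."""
        out = self.counts[:, :4].copy()
        out[:, 1] += self.counts[:, 4]
        return out

    def e_fraction(self, column: int) -> float:
        """E / (C + E) at a column; NaN when the column has no cytosine."""
        c = self.counts[column, 1]
        e = self.counts[column, 4]
        if c + e == 0:
            return float("nan")
        return e / (c + e)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for i, b in enumerate(EXTENDED_ALPHABET):
                fh.write(b + "\t" + "\t".join(str(v) for v in self.counts[:, i]) + "\n")


def site_methylation(site: BindingSite, track: MethylomeTrack) -> float:
    """Maximum defined CpG level overlapping the site interval; NaN if none.

    A merged CpG unit anchored at position p spans [p, p+2), so a unit one
    base left of the site still overlaps it.
    """
    span = track.unit_span
    start = max(site.start - (span - 1), 0)
    pos, levels = track.query_interval(site.peak.chrom, start, site.end)
    keep = pos + span > site.start
    levels = levels[keep]
    if len(levels) == 0:
        return float("nan")
    return float(np.max(levels))


def group_site(
    level: float, thresholds: PipelineThresholds = PipelineThresholds()
) -> str:
    """high iff level > site_high; low iff level < site_low; middle
    otherwise; no_cpg for an undefined level."""
    if level is None or math.isnan(level):
        return "no_cpg"
    if level > thresholds.site_high:
        return "high"
    if level < thresholds.site_low:
        return "low"
    return "middle"


def locate_binding_sites(
    hi_peaks: Sequence[Peak],
    low_peaks: Sequence[Peak],
    pwm_hi: Pwm,
    pwm_low: Pwm,
    genome: GenomeSequence,
    track: Optional[MethylomeTrack] = None,
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> Dict[str, List[BindingSite]]:
    """Relocate one best site per peak, scanning each methylation group
    with its own motif.

    Returns ``{'hi': [...], 'low': [...]}``.  Peaks shorter than the PWM
    or without an N-free placement are skipped with a logged count.  When a
    methylome track is supplied, each site also gets its methylation level
    and group.
    """
    ids_hi = {id(p) for p in hi_peaks}
    if ids_hi & {id(p) for p in low_peaks}:
        raise ValueError("hi and low peak groups must be disjoint")

    out: Dict[str, List[BindingSite]] = {"hi": [], "low": []}
    n_skipped = 0
    for group, peaks, pwm in (("hi", hi_peaks, pwm_hi), ("low", low_peaks, pwm_low)):
        for peak in peaks:
            seq = genome.get(peak.chrom, "")[peak.start : peak.end]
            if len(seq) < peak.length:
                n_skipped += 1
                continue
            try:
                hit = scan_peak(pwm, seq)
            except ValueError:
                n_skipped += 1
                continue
            site = BindingSite(
                peak=peak,
                start=peak.start + hit.offset,
                strand=hit.strand,
                score=hit.score,
                sequence=seq[hit.offset : hit.offset + pwm.length].upper(),
            )
            if track is not None:
                site.site_methylation = site_methylation(site, track)
                site.methyl_group = group_site(site.site_methylation, thresholds)
            out[group].append(site)
    if n_skipped:
        logger.info("skipped %d unscannable peaks", n_skipped)
    return out


def cpg_site_fraction(sites: Sequence[BindingSite]) -> float:
    """Fraction of sites whose (forward) sequence contains a CpG dinucleotide."""
    if not sites:
        raise ValueError("no binding sites")
    return sum("CG" in s.sequence for s in sites) / len(sites)


def annotate_e_sequence(
    site: BindingSite,
    track: MethylomeTrack,
    genome: GenomeSequence,
    e_threshold: float = 0.6,
) -> Optional[str]:
    """The site's reading-strand sequence with methylated CpG cytosines as E.

    Returns None (caller skips) when the sequence contains N.  Only
    CpG-context cytosines can become E; the CpG unit is looked up at the
    position of the + strand C of the dinucleotide, matching a
    strand-merged track (symmetric methylation).
    """
    reading = site.reading_sequence
    if "N" in reading:
        return None
    chrom_seq = genome[site.peak.chrom]
    out = []
    L = site.length
    for j, base in enumerate(reading):
        if base != "C":
            out.append(base)
            continue
        if site.strand == "+":
            g = site.start + j
            in_cpg = chrom_seq[g : g + 2] == "CG"
            unit_pos = g
        else:
            g = site.start + L - 1 - j  # genomic position of the complementary G
            in_cpg = chrom_seq[max(g - 1, 0) : g + 1] == "CG"
            unit_pos = g - 1
        if not in_cpg:
            out.append("C")
            continue
        _, levels = track.query_interval(site.peak.chrom, unit_pos, unit_pos + 1)
        if len(levels) and levels[0] > e_threshold:
            out.append("E")
        else:
            out.append("C")
    return "".join(out)


def rebuild_methyl_motif(
    sites: Sequence[BindingSite],
    track: MethylomeTrack,
    genome: GenomeSequence,
    e_threshold: float = 0.6,
) -> MethylMotif:
    """Accumulate per-column {A,C,G,T,E} counts over located sites.

    Sites are read 5'->3' on their binding strand; a CpG-context C whose
    unit level exceeds ``e_threshold`` counts as E.  N-containing sites are
    skipped with a logged count.
    """
    if not sites:
        raise ValueError("no binding sites")
    lengths = {s.length for s in sites}
    if len(lengths) != 1:
        raise ValueError(f"sites must share one length, got {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((L, 5), dtype=np.int64)
    idx = {b: i for i, b in enumerate(EXTENDED_ALPHABET)}
    n_used = 0
    n_skipped = 0
    for site in sites:
        annotated = annotate_e_sequence(site, track, genome, e_threshold)
        if annotated is None:
            n_skipped += 1
            continue
        for j, b in enumerate(annotated):
            counts[j, idx[b]] += 1
        n_used += 1
    if n_skipped:
        logger.info("skipped %d N-containing sites", n_skipped)
    if n_used == 0:
        raise ValueError("no usable (N-free) sites")
    return MethylMotif(counts=counts, n_sites=n_used)
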