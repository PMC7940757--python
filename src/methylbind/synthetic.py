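"""Synthetic genomes, methylomes, peak sets, and segmentations with known
ground truth.

The generator emulates the shape of the real study inputs: a genome with
CpG-enriched islands on a GC-defined background; a whole-genome bisulfite
methylome with per-cytosine read counts drawn Poisson x Binomial around
region-level regimes (island-low versus background-high, as in a
hypermethylated embryonic-stem-cell methylome); ChIP-seq narrowPeak
intervals centered near planted PWM occurrences plus occurrence-free noise
peaks; multi-cell-type peak sets following an explicit occupancy plan; and
a labeled block segmentation.  Every generator is deterministic given its
seed, and the truth (site coordinates, regimes, occupancy matrix, labels)
is returned alongside the emitted data so each pipeline stage can be
checked against what was planted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .io import CytosineRecord, GenomeSequence, Peak, SegmentInterval
from .motif import ALPHABET, Pwm, reverse_complement

logger = logging.getLogger(__name__)

#: (chrom, start, end, level) applied in order; later intervals override.
RegimeInterval = Tuple[str, int, int, float]


# ---------------------------------------------------------------------------
# genome


def make_genome(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 100_000,
    gc: float = 0.42,
    island_spec: Tuple[int, int, float] = (10, 1000, 5.0),
) -> Tuple[GenomeSequence, List[Tuple[str, int, int]]]:
    """An i.i.d. background genome with embedded CpG-enriched islands.

    ``island_spec`` is (count, length, cpg_enrichment); islands are evenly
    spaced along each chromosome and the per-position chance of emitting a
    CG dinucleotide inside an island is the background CpG rate times the
    enrichment.  Returns the genome and the island intervals.
    """
    if chrom_length < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    n_islands, island_len, enrichment = island_spec
    rng = np.random.default_rng(seed)
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bg_cpg_rate = (gc / 2) ** 2
    p_cg = min(0.4, bg_cpg_rate * enrichment)
    island_gc = min(0.9, gc + 0.15)
    p_island = np.array(
        [(1 - island_gc) / 2, island_gc / 2, island_gc / 2, (1 - island_gc) / 2]
    )

    per_chrom = [n_islands // n_chroms + (1 if c < n_islands % n_chroms else 0) for c in range(n_chroms)]
    genome: GenomeSequence = {}
    islands: List[Tuple[str, int, int]] = []
    bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        codes = rng.choice(4, size=chrom_length, p=p_bg)
        k = per_chrom[c]
        if k:
            stride = chrom_length // (k + 1)
            if island_len >= stride or island_len >= chrom_length:
                raise ValueError("islands exceed chromosome length")
            for i in range(k):
                start = stride * (i + 1)
                islands.append((chrom, start, start + island_len))
                # sequential draw so CG dinucleotides appear at the planted rate
                j = start
                while j < start + island_len:
                    if j + 1 < start + island_len and rng.random() < p_cg:
                        codes[j], codes[j + 1] = 1, 2  # C, G
                        j += 2
                    else:
                        codes[j] = rng.choice(4, p=p_island)
                        j += 1
        genome[chrom] = bases[codes].tobytes().decode()
    return genome, islands


def cpg_positions(genome: GenomeSequence) -> Dict[str, np.ndarray]:
    """0-based positions of the C of every CG dinucleotide, per chromosome."""
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = arr[:-1] == ord("C")
        is_g = arr[1:] == ord("G")
        out[chrom] = np.nonzero(is_c & is_g)[0].astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# methylome


def make_methylome(
    genome: GenomeSequence,
    regime_map: Sequence[RegimeInterval],
    depth: float = 30.0,
    seed: int = 0,
    replicates: int = 1,
    background_level: float = 0.75,
) -> List[List[CytosineRecord]]:
    """Binomially sampled per-cytosine records for every CpG in the genome.

    Each CpG cytosine (both strands) receives ``total ~ Poisson(depth/2)``
    reads — so a strand-merged CpG unit averages ``depth`` reads — and
    ``meth ~ Binomial(total, m)`` where m is the regime mean at the locus
    (``background_level`` outside every regime interval; later regime
    intervals override earlier ones).  With ``replicates=2`` the reads of
    each locus are split between two half-depth replicates whose merged
    counts reproduce the single-file totals exactly.
    """
    if replicates not in (1, 2):
        raise ValueError("replicates must be 1 or 2")
    for _, _, _, level in regime_map:
        if not (0.0 <= level <= 1.0):
            raise ValueError("regime means must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    # separate stream for the replicate split so the sampled per-locus totals
    # are identical whether one or two replicates are emitted
    split_rng = np.random.default_rng([seed, 1])
    reps: List[List[CytosineRecord]] = [[] for _ in range(replicates)]
    cpgs = cpg_positions(genome)
    regimes_by_chrom: Dict[str, List[RegimeInterval]] = {}
    for r in regime_map:
        regimes_by_chrom.setdefault(r[0], []).append(r)

    for chrom in genome:
        pos = cpgs[chrom]
        if len(pos) == 0:
            continue
        levels = np.full(len(pos), background_level)
        for _, start, end, level in regimes_by_chrom.get(chrom, []):
            levels[(pos >= start) & (pos < end)] = level
        for strand, p_strand in (("+", pos), ("-", pos + 1)):
            totals = rng.poisson(depth / 2.0, size=len(pos))
            meths = rng.binomial(totals, levels)
            if replicates == 1:
                reps[0].extend(
                    CytosineRecord(chrom, int(p), strand, int(m), int(t))
                    for p, m, t in zip(p_strand, meths, totals)
                )
            else:
                # exact read split: tot_a of the reads go to replicate A,
                # the methylated ones among them hypergeometrically
                tot_a = split_rng.binomial(totals, 0.5)
                meth_a = np.zeros(len(pos), dtype=np.int64)
                nz = totals > 0
                if nz.any():
                    meth_a[nz] = split_rng.hypergeometric(meths[nz], totals[nz] - meths[nz], tot_a[nz])
                reps[0].extend(
                    CytosineRecord(chrom, int(p), strand, int(m), int(t))
                    for p, m, t in zip(p_strand, meth_a, tot_a)
                )
                reps[1].extend(
                    CytosineRecord(chrom, int(p), strand, int(m), int(t))
                    for p, m, t in zip(p_strand, meths - meth_a, totals - tot_a)
                )
    for rep in reps:
        rep.sort(key=lambda r: (r.chrom, r.pos, r.strand))
    return reps


# ---------------------------------------------------------------------------
# slot allocation (non-overlapping placements shared across generators)


class SlotAllocator:
    """Hands out non-overlapping, well-separated placement slots.

    Candidate slot starts lie on a fixed grid (one per ``spacing`` bp,
    offset by ``margin``); slots overlapping an excluded interval are
    removed up front.  ``take`` consumes random free slots, so placements
    from successive calls never collide.
    """

    def __init__(
        self,
        chrom_lengths: Dict[str, int],
        spacing: int = 3600,
        margin: int = 200,
        exclude: Sequence[Tuple[str, int, int]] = (),
    ):
        self.spacing = spacing
        self.margin = margin
        self._free: List[Tuple[str, int]] = []
        excl: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in exclude:
            excl.setdefault(chrom, []).append((s, e))
        for chrom, length in chrom_lengths.items():
            for start in range(margin, length - spacing, spacing):
                slot = (start, start + spacing - margin)
                if any(s < slot[1] + margin and slot[0] - margin < e for s, e in excl.get(chrom, [])):
                    continue
                self._free.append((chrom, start))

    @property
    def n_free(self) -> int:
        return len(self._free)

    def take(self, n: int, rng: np.random.Generator) -> List[Tuple[str, int]]:
        if n > len(self._free):
            raise ValueError(f"requested {n} slots but only {len(self._free)} free")
        idx = rng.choice(len(self._free), size=n, replace=False)
        chosen = [self._free[i] for i in idx]
        for i in sorted(idx, reverse=True):
            self._free.pop(int(i))
        return chosen


# ---------------------------------------------------------------------------
# planted peaks


@dataclass
class PlantedSite:
    chrom: str
    start: int  # genomic start of the planted occurrence
    strand: str
    peak_name: str
    group: str  # planned methylation group of the peak ('hi'/'low')


@dataclass
class PlantResult:
    genome: GenomeSequence  # genome with occurrences written in
    peaks: List[Peak]  # planted peaks followed by noise peaks
    sites: List[PlantedSite]  # one per planted (non-noise) peak
    regimes: List[RegimeInterval]


_CONDITIONS = {
    "site_methylated": {"peak_level": 0.65, "site_level": 0.95},
    "site_unmethylated": {"peak_level": 0.08, "site_level": 0.03},
}


def plant_peaks(
    genome: GenomeSequence,
    pwm: Pwm,
    n_sites: int,
    methyl_condition: str = "site_methylated",
    n_noise_peaks: int = 0,
    peak_width: int = 200,
    seed: int = 0,
    allocator: Optional[SlotAllocator] = None,
    peak_level: Optional[float] = None,
    site_level: Optional[float] = None,
    core_pad: int = 20,
    jitter_frac: float = 0.25,
    group: str = "hi",
    name_prefix: str = "peak",
) -> PlantResult:
    """Plant PWM occurrences and emit peaks centered near them.

    Each planted peak contains exactly one occurrence sampled from the PWM
    (random strand) written into the genome; the peak interval is centered
    on the occurrence plus a uniform jitter up to ``jitter_frac`` of the
    width, so the summit does not coincide with the site and relocation is
    exercised.  ``methyl_condition`` sets default methylation regimes: the
    peak interval at ``peak_level`` and a core of ``site +- core_pad`` bp
    at ``site_level`` (both overridable).  Noise peaks get no occurrence
    and no regime.
    """
    if methyl_condition not in _CONDITIONS:
        raise ValueError(f"unknown methyl_condition {methyl_condition!r}")
    defaults = _CONDITIONS[methyl_condition]
    peak_level = defaults["peak_level"] if peak_level is None else peak_level
    site_level = defaults["site_level"] if site_level is None else site_level

    rng = np.random.default_rng(seed)
    L = pwm.length
    if allocator is None:
        allocator = SlotAllocator({c: len(s) for c, s in genome.items()})
    slots = allocator.take(n_sites + n_noise_peaks, rng)

    mutable = {c: bytearray(s.encode()) for c, s in genome.items()}
    peaks: List[Peak] = []
    sites: List[PlantedSite] = []
    regimes: List[RegimeInterval] = []
    max_jit = int(jitter_frac * peak_width)
    max_jit = min(max_jit, peak_width // 2 - L - 1)

    for i in range(n_sites):
        chrom, anchor = slots[i]
        site_start = anchor + peak_width // 2  # leave room for the jittered peak
        sampled = "".join(
            ALPHABET[rng.choice(4, p=pwm.probs[j])] for j in range(L)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        written = sampled if strand == "+" else reverse_complement(sampled)
        mutable[chrom][site_start : site_start + L] = written.encode()
        site_center = site_start + L // 2
        jit = int(rng.integers(-max_jit, max_jit + 1))
        p_start = site_center + jit - peak_width // 2
        name = f"{name_prefix}_{i:05d}"
        peaks.append(
            Peak(chrom=chrom, start=p_start, end=p_start + peak_width, name=name, summit=peak_width // 2)
        )
        sites.append(PlantedSite(chrom, site_start, strand, name, group))
        regimes.append((chrom, p_start, p_start + peak_width, peak_level))
        regimes.append((chrom, site_start - core_pad, site_start + L + core_pad, site_level))

    for i in range(n_noise_peaks):
        chrom, anchor = slots[n_sites + i]
        p_start = anchor + peak_width // 4
        peaks.append(
            Peak(
                chrom=chrom,
                start=p_start,
                end=p_start + peak_width,
                name=f"{name_prefix}_noise_{i:05d}",
                summit=peak_width // 2,
            )
        )

    out_genome = {c: b.decode() for c, b in mutable.items()}
    return PlantResult(genome=out_genome, peaks=peaks, sites=sites, regimes=regimes)


# ---------------------------------------------------------------------------
# multi-cell occupancy


@dataclass
class MulticellResult:
    cell_peaks: List[List[Peak]]  # one list per non-reference cell
    occupancy: np.ndarray  # (n_peaks, n_cells) bool; column 0 = reference


def make_multicell(
    base_peaks: Sequence[Peak],
    n_cells: int,
    occupancy_plan: Union[np.ndarray, Sequence[float]],
    jitter: int = 0,
    seed: int = 0,
) -> MulticellResult:
    """Per-cell peak sets realising an occupancy plan.

    ``occupancy_plan`` is either an explicit (n_peaks, n_cells) boolean
    matrix (column 0, the reference, must be all True) or a per-peak
    probability with which each non-reference cell carries the peak.  Cell
    copies are shifted by a uniform jitter up to ``jitter`` bp (must be
    smaller than the peak width, so overlap with the reference persists).
    """
    n_peaks = len(base_peaks)
    rng = np.random.default_rng(seed)
    plan = np.asarray(occupancy_plan)
    if plan.ndim == 1:
        if len(plan) != n_peaks:
            raise ValueError("one occupancy probability per peak required")
        matrix = np.ones((n_peaks, n_cells), dtype=bool)
        matrix[:, 1:] = rng.random((n_peaks, n_cells - 1)) < plan[:, None]
    else:
        matrix = plan.astype(bool)
        if matrix.shape != (n_peaks, n_cells):
            raise ValueError(f"plan shape {matrix.shape} != ({n_peaks}, {n_cells})")
        if not matrix[:, 0].all():
            raise ValueError("reference column of the occupancy plan must be all True")
    widths = {p.length for p in base_peaks}
    if jitter and jitter >= min(widths):
        raise ValueError("jitter must be smaller than the peak width")

    cell_peaks: List[List[Peak]] = []
    for c in range(1, n_cells):
        cell: List[Peak] = []
        for i, p in enumerate(base_peaks):
            if not matrix[i, c]:
                continue
            shift = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            cell.append(
                Peak(
                    chrom=p.chrom,
                    start=p.start + shift,
                    end=p.end + shift,
                    name=f"{p.name}_cell{c}",
                    summit=p.summit,
                )
            )
        cell_peaks.append(cell)
    return MulticellResult(cell_peaks=cell_peaks, occupancy=matrix)


# ---------------------------------------------------------------------------
# segmentation


def make_segmentation(
    peaks: Sequence[Peak],
    groups: Sequence[str],
    chrom_lengths: Dict[str, int],
    enhancer_rate_hi: float = 0.8,
    enhancer_rate_low: float = 0.3,
    pad: int = 300,
    seed: int = 0,
    enhancer_label: str = "7_Enhancer",
    promoter_label: str = "1_Active_Promoter",
    fill_label: str = "15_Quiescent",
) -> Tuple[List[SegmentInterval], Dict[str, str]]:
    """A block segmentation covering each peak (± pad) with an
    enhancer/promoter label drawn at a group-dependent rate, and quiescent
    fill everywhere else.  Returns the segments and the per-peak label
    truth."""
    if len(peaks) != len(groups):
        raise ValueError("one group per peak required")
    rng = np.random.default_rng(seed)
    blocks: Dict[str, List[Tuple[int, int, str]]] = {c: [] for c in chrom_lengths}
    truth: Dict[str, str] = {}
    for peak, group in zip(peaks, groups):
        rate = enhancer_rate_hi if group == "hi" else enhancer_rate_low
        label = enhancer_label if rng.random() < rate else promoter_label
        truth[peak.name] = label
        start = max(peak.start - pad, 0)
        end = min(peak.end + pad, chrom_lengths[peak.chrom])
        blocks[peak.chrom].append((start, end, label))

    segments: List[SegmentInterval] = []
    for chrom, length in chrom_lengths.items():
        cursor = 0
        for start, end, label in sorted(blocks[chrom]):
            if start > cursor:
                segments.append(SegmentInterval(chrom, cursor, start, fill_label))
            segments.append(SegmentInterval(chrom, max(start, cursor), end, label))
            cursor = end
        if cursor < length:
            segments.append(SegmentInterval(chrom, cursor, length, fill_label))
    return segments, truth


# ---------------------------------------------------------------------------
# manifest


def write_manifest(params: Dict, path: Union[str, Path]) -> None:
    """Record generator parameters and seeds for reproducibility."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
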