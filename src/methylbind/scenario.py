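"""The packaged end-to-end study: two TF archetypes on a synthetic genome.

``simulate_study`` generates a complete input set with known truth and
``analyze_study`` runs every pipeline stage over it:

* a *methyl-preferring* TF (CEBPB-like): its hi-methyl peaks carry a
  CpG-bearing motif variant whose CpG is highly methylated, and the
  methylation metaplot rises at the site center;
* a *methyl-avoiding* TF (CTCF-like): it binds hi-methyl regions with a
  CpG-depleted motif variant, the site-core CpGs stay unmethylated, and
  the metaplot dips at the center;
* island-low / background-high methylation regimes (an embryonic-stem-cell
  flavoured methylome), DNase hypersensitive sites split between the two
  regimes, an enhancer-enriched segmentation for hi peaks, and a six-cell
  occupancy plan under which hi-methyl peaks of the methyl-avoiding TF are
  rarely conserved.

Default sizes (500 planted peaks per TF, ~30x CpG coverage, 5.2 Mb
genome) keep a full run near a minute while leaving every estimated
fraction with a usable standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import SegmentationIndex, assign_chromatin_state, dhs_methylated_fraction, state_composition
from .conserve import conservation_records, conserved_fraction_by_group
from .io import GeneInterval, GenomeSequence, Peak, SegmentInterval
from .methylome import MethylomeTrack, build_track, merge_replicates
from .motif import Pwm, build_pwm
from .peaks import PeakMethylation, PipelineThresholds, himethyl_fraction, peak_mean_methylation
from .profiles import MethylationProfile, flank_profile
from .sites import BindingSite, cpg_site_fraction, locate_binding_sites, rebuild_methyl_motif
from .synthetic import (
    MulticellResult,
    PlantedSite,
    SlotAllocator,
    make_genome,
    make_methylome,
    make_multicell,
    make_segmentation,
    plant_peaks,
)


def _consensus_pwm(consensus: str, strong: float = 0.95, overrides: Dict[int, Dict[str, float]] = {}) -> Pwm:
    """PWM with ``strong`` probability on the consensus base, optionally
    overriding whole columns with explicit base->probability maps."""
    from .motif import ALPHABET, UNIFORM_BACKGROUND

    L = len(consensus)
    probs = np.full((L, 4), (1 - strong) / 3)
    for j, b in enumerate(consensus):
        probs[j, ALPHABET.index(b)] = strong
    for j, col in overrides.items():
        probs[j] = [(col.get(b, 0.0)) for b in ALPHABET]
        rest = 1.0 - probs[j].sum()
        probs[j] += rest / 4  # distribute any remainder evenly
    probs /= probs.sum(axis=1, keepdims=True)
    return Pwm(probs=probs, background=UNIFORM_BACKGROUND.copy())


@dataclass
class Archetype:
    """One simulated TF: motif variants per methylation group plus sizes."""

    name: str
    mode: str  # 'methyl_preferring' or 'methyl_avoiding'
    pwm_hi: Pwm
    pwm_low: Pwm
    cpg_column: int  # C position of the planted CpG (reading strand)
    n_hi: int
    n_low: int
    n_noise: int
    # regime levels for the hi group (low group always 0.08 / 0.03)
    hi_peak_level: float = 0.65
    hi_site_level: float = 0.95
    hi_core_pad: int = 20  # half-width of the site-core regime beyond the site
    conserved_rate_hi: float = 0.42
    conserved_rate_low: float = 0.37


def default_archetypes(n_peaks_per_tf: int = 500, n_noise: int = 25) -> List[Archetype]:
    """The two study archetypes at their default sizes."""
    preferring = Archetype(
        name="TF_methyl_preferring",
        mode="methyl_preferring",
        # CpG at columns 4-5; the hi variant carries it, the low variant mostly not
        pwm_hi=_consensus_pwm("TTGACGTCAT", overrides={4: {"C": 0.9, "T": 0.04, "A": 0.03, "G": 0.03},
                                                       5: {"G": 0.95, "A": 0.02, "C": 0.015, "T": 0.015}}),
        pwm_low=_consensus_pwm("TTGATGTCAT", overrides={4: {"T": 0.55, "C": 0.25, "A": 0.1, "G": 0.1}}),
        cpg_column=4,
        n_hi=int(round(0.55 * n_peaks_per_tf)),
        n_low=n_peaks_per_tf - int(round(0.55 * n_peaks_per_tf)),
        n_noise=n_noise,
        hi_peak_level=0.65,
        hi_site_level=0.95,  # the planted CpG is methylated -> E calls, center rise
        conserved_rate_hi=0.42,
        conserved_rate_low=0.37,
    )
    avoiding = Archetype(
        name="TF_methyl_avoiding",
        mode="methyl_avoiding",
        # CpG at columns 2-3 in the low variant; depleted in the hi variant
        pwm_hi=_consensus_pwm("AGTGCCATTA", overrides={2: {"T": 0.55, "C": 0.25, "A": 0.1, "G": 0.1},
                                                       3: {"G": 0.9, "A": 0.04, "C": 0.03, "T": 0.03}}),
        pwm_low=_consensus_pwm("AGCGCCATTA", overrides={2: {"C": 0.85, "T": 0.05, "A": 0.05, "G": 0.05},
                                                        3: {"G": 0.9, "A": 0.04, "C": 0.03, "T": 0.03}}),
        cpg_column=2,
        n_hi=int(round(0.3 * n_peaks_per_tf)),
        n_low=n_peaks_per_tf - int(round(0.3 * n_peaks_per_tf)),
        n_noise=n_noise,
        hi_peak_level=0.9,
        hi_site_level=0.05,  # site core stays unmethylated -> center dip
        # narrow core: the dip is visible at 25 bp bins without dragging
        # whole-peak CpG means below the hi cutoff
        hi_core_pad=10,
        conserved_rate_hi=0.19,
        conserved_rate_low=0.67,
    )
    return [preferring, avoiding]


@dataclass
class TfTruth:
    archetype: Archetype
    peaks: List[Peak]  # planted hi + planted low + noise, in that order
    planted_sites: List[PlantedSite]
    truth_groups: List[str]  # planned group per peak ('hi'/'low'; noise peaks 'hi')
    multicell: Optional[MulticellResult] = None


@dataclass
class Study:
    """Everything the pipeline consumes plus the generator truth."""

    seed: int
    genome: GenomeSequence
    islands: List[Tuple[str, int, int]]
    track: MethylomeTrack
    replicates: Optional[List[List]] = None
    tfs: Dict[str, TfTruth] = field(default_factory=dict)
    segmentation: List[SegmentInterval] = field(default_factory=list)
    segmentation_truth: Dict[str, str] = field(default_factory=dict)
    dhs_peaks: List[Peak] = field(default_factory=list)
    dhs_truth_hi: List[bool] = field(default_factory=list)
    genes: List[GeneInterval] = field(default_factory=list)
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    n_cells: int = 6


ISLAND_LEVEL = 0.05
BACKGROUND_LEVEL = 0.75
LOW_PEAK_LEVEL = 0.08
LOW_SITE_LEVEL = 0.03


def simulate_study(
    seed: int,
    n_peaks_per_tf: int = 500,
    n_noise: int = 25,
    depth: float = 30.0,
    n_chroms: int = 2,
    chrom_length: int = 2_600_000,
    peak_width: int = 200,
    n_dhs_per_regime: int = 150,
    n_genes: int = 400,
    n_cells: int = 6,
    multicell_jitter: int = 0,
    two_replicates: bool = False,
) -> Study:
    """Generate the full two-archetype synthetic study, deterministically."""
    rng = np.random.default_rng(seed)
    n_islands = n_dhs_per_regime  # one island per island-DHS
    genome, islands = make_genome(
        seed=int(rng.integers(2**31)),
        n_chroms=n_chroms,
        chrom_length=chrom_length,
        gc=0.42,
        island_spec=(n_islands, 2000, 5.0),
    )
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    # keep placements a full metaplot flank away from islands so flank
    # profiles see only the regimes planted for their own peak
    flank = PipelineThresholds().flank_bp
    inflated = [(c, max(s - flank, 0), e + flank) for c, s, e in islands]
    allocator = SlotAllocator(chrom_lengths, spacing=2400, margin=200, exclude=inflated)

    regimes: List[Tuple[str, int, int, float]] = [
        (c, s, e, ISLAND_LEVEL) for c, s, e in islands
    ]
    tfs: Dict[str, TfTruth] = {}
    for arch in default_archetypes(n_peaks_per_tf, n_noise):
        hi = plant_peaks(
            genome,
            arch.pwm_hi,
            n_sites=arch.n_hi,
            methyl_condition="site_methylated",
            peak_width=peak_width,
            seed=int(rng.integers(2**31)),
            allocator=allocator,
            peak_level=arch.hi_peak_level,
            site_level=arch.hi_site_level,
            core_pad=arch.hi_core_pad,
            group="hi",
            name_prefix=f"{arch.name}_hi",
        )
        genome = hi.genome
        low = plant_peaks(
            genome,
            arch.pwm_low,
            n_sites=arch.n_low,
            methyl_condition="site_unmethylated",
            n_noise_peaks=arch.n_noise,
            peak_width=peak_width,
            seed=int(rng.integers(2**31)),
            allocator=allocator,
            peak_level=LOW_PEAK_LEVEL,
            site_level=LOW_SITE_LEVEL,
            group="low",
            name_prefix=f"{arch.name}_low",
        )
        genome = low.genome
        regimes.extend(hi.regimes)
        regimes.extend(low.regimes)
        planted_peaks = hi.peaks + low.peaks[: arch.n_low]
        noise_peaks = low.peaks[arch.n_low :]
        # noise peaks sit on the hyper-methylated background -> planned 'hi'
        truth_groups = ["hi"] * arch.n_hi + ["low"] * arch.n_low + ["hi"] * len(noise_peaks)
        tfs[arch.name] = TfTruth(
            archetype=arch,
            peaks=planted_peaks + noise_peaks,
            planted_sites=hi.sites + low.sites,
            truth_groups=truth_groups,
        )

    # DNase hypersensitive sites: half on the methylated background, half in
    # unmethylated islands (planned methylated fraction = one half)
    dhs: List[Peak] = []
    dhs_truth: List[bool] = []
    for i, (chrom, anchor) in enumerate(allocator.take(n_dhs_per_regime, rng)):
        dhs.append(Peak(chrom, anchor, anchor + peak_width, name=f"dhs_bg_{i:04d}"))
        dhs_truth.append(True)
    for i, (chrom, s, e) in enumerate(islands[:n_dhs_per_regime]):
        mid = (s + e) // 2
        dhs.append(
            Peak(chrom, mid - peak_width // 2, mid + peak_width // 2, name=f"dhs_island_{i:04d}")
        )
        dhs_truth.append(False)

    reps = make_methylome(
        genome,
        regimes,
        depth=depth,
        seed=int(rng.integers(2**31)),
        replicates=2 if two_replicates else 1,
        background_level=BACKGROUND_LEVEL,
    )
    records = merge_replicates(reps[0], reps[1]) if two_replicates else reps[0]
    track = build_track(records, merge_cpg_strands=True, genome=genome)

    # segmentation over both TFs' peaks: enhancer-enriched for hi peaks
    all_peaks: List[Peak] = []
    all_groups: List[str] = []
    for tf in tfs.values():
        all_peaks.extend(tf.peaks)
        all_groups.extend(tf.truth_groups)
    segmentation, seg_truth = make_segmentation(
        all_peaks, all_groups, chrom_lengths, seed=int(rng.integers(2**31))
    )

    # six-cell occupancy plans per TF over the planted peaks
    for tf in tfs.values():
        arch = tf.archetype
        n_planted = arch.n_hi + arch.n_low
        plan = np.ones((n_planted, n_cells), dtype=bool)
        plan_rng = np.random.default_rng(int(rng.integers(2**31)))
        for i in range(n_planted):
            rate = arch.conserved_rate_hi if tf.truth_groups[i] == "hi" else arch.conserved_rate_low
            if plan_rng.random() < rate:
                k_other = int(plan_rng.integers(4, n_cells))  # k/N > 0.8
            else:
                k_other = int(plan_rng.integers(0, 4))  # k/N <= 0.8
            cells = plan_rng.choice(n_cells - 1, size=k_other, replace=False) + 1
            row = np.zeros(n_cells, dtype=bool)
            row[0] = True
            row[cells] = True
            plan[i] = row
        tf.multicell = make_multicell(
            tf.peaks[:n_planted],
            n_cells,
            plan,
            jitter=multicell_jitter,
            seed=int(rng.integers(2**31)),
        )

    # random gene annotation (may overlap anything)
    genes: List[GeneInterval] = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_lengths[chrom] - 2000))
        genes.append(GeneInterval(chrom, start, start + 1500, f"gene{i:04d}", "+"))

    return Study(
        seed=seed,
        genome=genome,
        islands=islands,
        track=track,
        replicates=reps,
        tfs=tfs,
        segmentation=segmentation,
        segmentation_truth=seg_truth,
        dhs_peaks=dhs,
        dhs_truth_hi=dhs_truth,
        genes=genes,
        n_cells=n_cells,
    )


@dataclass
class TfAnalysis:
    """Pipeline outputs for one TF of the study."""

    peak_meths: List[PeakMethylation]
    hi_fraction: float
    truth_hi_fraction: float
    sites: Dict[str, List[BindingSite]]
    relocation_within_2bp: float
    cpg_fraction_hi: float
    cpg_fraction_low: float
    e_fraction_at_cpg_column: float
    profile_hi: MethylationProfile
    profile_low: MethylationProfile
    conserved_fractions: Dict[str, float]
    conserved_truth: Dict[str, float]
    state_fractions: Dict[str, Dict[str, float]]


def _relocation_accuracy(
    located: Dict[str, List[BindingSite]], planted: Sequence[PlantedSite], tol_bp: int = 2
) -> float:
    truth = {s.peak_name: s for s in planted}
    n_eval = 0
    n_hit = 0
    for group_sites in located.values():
        for site in group_sites:
            t = truth.get(site.peak.name)
            if t is None:  # noise peak
                continue
            n_eval += 1
            if abs(site.start - t.start) <= tol_bp:
                n_hit += 1
    return n_hit / n_eval if n_eval else float("nan")


def analyze_tf(study: Study, name: str, seed: int = 0) -> TfAnalysis:
    """Run every stage of the pipeline for one simulated TF."""
    tf = study.tfs[name]
    arch = tf.archetype
    th = study.thresholds
    meths = [peak_mean_methylation(p, study.track, th) for p in tf.peaks]
    hi_frac = himethyl_fraction(meths)
    truth_hi = sum(g == "hi" for g in tf.truth_groups) / len(tf.truth_groups)

    hi_peaks = [m.peak for m in meths if m.group == "hi"]
    low_peaks = [m.peak for m in meths if m.group == "low"]
    located = locate_binding_sites(
        hi_peaks, low_peaks, arch.pwm_hi, arch.pwm_low, study.genome, study.track, th
    )
    reloc = _relocation_accuracy(located, tf.planted_sites)

    cpg_hi = cpg_site_fraction(located["hi"]) if located["hi"] else float("nan")
    cpg_low = cpg_site_fraction(located["low"]) if located["low"] else float("nan")

    motif_hi = rebuild_methyl_motif(located["hi"], study.track, study.genome, e_threshold=th.site_high)
    e_frac = motif_hi.e_fraction(arch.cpg_column)

    prof_hi = flank_profile(located["hi"], study.track, flank=th.flank_bp, bin_width=25)
    prof_low = flank_profile(located["low"], study.track, flank=th.flank_bp, bin_width=25)

    # conservation over the planted peaks, grouped by measured methylation
    n_planted = arch.n_hi + arch.n_low
    planted_meths = meths[:n_planted]
    levels = [m.mean_level for m in planted_meths]
    groups = [m.group for m in planted_meths]
    assert tf.multicell is not None
    records = conservation_records(tf.peaks[:n_planted], levels, tf.multicell.cell_peaks, th)
    cons = conserved_fraction_by_group(records, groups)
    # plan-derived truth with the same grouping
    k = tf.multicell.occupancy.sum(axis=1)
    conserved_truth_flags = k / study.n_cells > th.conserved_occupancy
    truth_cons: Dict[str, float] = {}
    for g in sorted(set(groups)):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        truth_cons[g] = float(np.mean(conserved_truth_flags[idx]))

    index = SegmentationIndex(study.segmentation)
    assignments = {
        "hi": [assign_chromatin_state(p, index) for p in hi_peaks],
        "low": [assign_chromatin_state(p, index) for p in low_peaks],
    }
    states = state_composition(assignments)

    return TfAnalysis(
        peak_meths=meths,
        hi_fraction=hi_frac,
        truth_hi_fraction=truth_hi,
        sites=located,
        relocation_within_2bp=reloc,
        cpg_fraction_hi=cpg_hi,
        cpg_fraction_low=cpg_low,
        e_fraction_at_cpg_column=e_frac,
        profile_hi=prof_hi,
        profile_low=prof_low,
        conserved_fractions=cons,
        conserved_truth=truth_cons,
        state_fractions=states,
    )


def analyze_study(study: Study, seed: int = 0) -> Dict[str, TfAnalysis]:
    return {name: analyze_tf(study, name, seed) for name in study.tfs}


def study_dhs_methylated_fraction(study: Study) -> float:
    return dhs_methylated_fraction(study.dhs_peaks, study.track, study.thresholds)
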