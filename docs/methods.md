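# Methods

## Data model and conventions

All intervals are 0-based half-open (BED convention); chromosome names are
matched exactly, with no `chr`-prefix normalization — a naming mismatch
surfaces as an empty, logged query rather than silently renamed data.
Methylation input must be a count dialect (methylated/total or
methylated/unmethylated read counts per cytosine); percentage-only files
are rejected because replicate merging sums read counts, which a
percentage cannot support.

The methylation level of a locus is β = m/t.  Replicates are merged by
summing m and t per locus before any ratio is formed.  By default the two
symmetric cytosines of a CpG dinucleotide are merged into one *CpG unit*
anchored at the + strand C (counts summed), on the assumption of symmetric
CpG methylation; downstream statistics reason about CpG sites, and
per-strand cytosines would double-count dinucleotides.  A per-strand mode
exists for asymmetry analyses.  Units with coverage below `min_coverage`
(default 1 read) have undefined β and are excluded from every statistic: a
ratio over zero reads is undefined, and coverage filtering is
conventional.  Non-CpG cytosines (CHG/CHH) are dropped with a logged
count; only CpG methylation is analysed.

## Peak methylation and classification

A peak's methylation is the *unweighted* mean β̄ over the CpG units inside
it — per-site averaging, not read-weighted, so a single deeply covered CpG
cannot dominate.  Classification is strict: hi-methyl iff β̄ > 0.6;
exactly 0.6 is low.  Peaks containing no covered CpG are *unassigned* and
excluded from both numerator and denominator of hi-methyl fractions — a
methylation statement about a CpG-free interval is vacuous.  Dataset-level
filtering keeps experiments with ≥ 500 peaks and, among multiple
experiments for one (TF, cell type), the one with the most peaks
(peak-count ties go to the lexicographically smallest dataset id, logged).

## Motifs and binding-site relocation

PWMs are estimated with a pseudocount (default 0.5 per cell):
p_j(b) = (n_j(b) + c) / (n + 4c).  Scores are log₂ odds against a
mononucleotide background (genome-wide base frequencies of the supplied
FASTA; uniform when absent).  Scanning evaluates every offset on both
strands (reverse strand scored on the reverse complement) and returns the
single best placement; ties break deterministically to the smaller offset,
then the + strand.  Placements containing N are skipped rather than
penalized; peaks with no N-free placement are dropped with a logged count.

De novo discovery is a seeded ZOOPS-style hard EM: k-mers most
overrepresented against per-sequence mononucleotide shuffles seed
candidate PWMs (consensus probability 0.7), each refined by alternating
best-site assignment and re-estimation until the maximum absolute
probability change falls below 1e-4 (or 100 rounds).  Candidates are
ranked by *enrichment*: mean best-site log-odds on the real sequences
minus the same on the shuffled ones, so composition-only motifs score near
zero.  Discovery is bit-reproducible given its seed.  Absolute score
scales are tool-specific; only argmax/rank behaviour (which drives
relocation) is treated as transferable, and JASPAR-style matrices can be
imported to bypass discovery entirely.

Relocation scans each methylation group's peaks with that group's motif
and takes the best placement per peak as *the* binding site.

## Site methylation, grouping and the E alphabet

A site's methylation is the **maximum** β over CpG units overlapping the
site interval (a merged unit at p spans [p, p+2), so a unit one base left
of the site still overlaps): a site with several CpGs is called methylated
if any of them is.  Sites group as high (β > 0.6), low (β < 0.2), middle
(otherwise) or no_cpg (no overlapping unit); both boundary values are
middle.

Methylation-aware motifs re-read each site 5′→3′ on its binding strand
(− strand sites reverse-complemented; their methylation is read from the
strand-merged unit, i.e. the symmetric-methylation assumption again).  A
cytosine is recorded as E iff it sits in CpG context *on the reading
strand* and its unit's β exceeds `e_threshold`; all other bases are
recorded verbatim.  `e_threshold` defaults to the site-high cutoff (0.6),
aligning the E call with site grouping; no independent value is claimed
for it.  A methylated non-CpG cytosine is never E.  Collapsing E back
onto C reproduces exactly the plain base counts of the same sites — a
tested invariant.

## Metaplots

Profiles aggregate β by signed offset from the *site center* (midpoint of
the relocated site, not the peak summit — the quantity of interest is
methylation around the bound sequence).  Offsets of − strand sites are
negated so profiles are oriented 5′→3′.  The window is ±1600 bp with
25 bp bins (the window half-width follows the analysis convention for
this kind of metaplot; the bin width is a display/aggregation choice with
no analytic significance, giving 64 bins per side).  Each CpG contributes
once per overlapping site window; overlapping windows intentionally
double-count shared CpGs, as metaplots conventionally do.  Bins with no
contribution have undefined means.  The hi − low contrast carries 95%
bands from resampling sites with replacement (200 replicates, seeded).

## Chromatin states and DHS methylation

Each peak gets the single segmentation label with the largest total
base-pair overlap (majority rule; label ties break lexicographically;
segments may overlap or leave gaps and are never merged).  Peaks with no
overlapping segment are `Unannotated` with overlap fraction 1.0 — the
whole peak is unannotated.  Label strings are verbatim; an optional
two-column mapping file coarsens chromHMM mnemonics to classes.  An
all-overlapping-labels mode is not provided; the majority rule is the
design choice, and splitting a segment into same-label pieces provably
cannot change an assignment.  DHS methylated fractions reuse peak
classification unchanged: the fraction of DNase peaks with β̄ > 0.6.

## Conservation across cell types

Occupancy k of a reference peak counts the surveyed cell types — the
reference included — whose peak set overlaps it by ≥ 1 bp (no
reciprocal-overlap requirement; half-open intervals, so abutting peaks do
not overlap).  Conserved iff k/N > 0.8, strictly: with six cells, 5/6 is
conserved and 4/6 is not.  "More than 80% of occupied cells" admits other
readings; this package fixes the occupancy-fraction reading and exposes
the threshold (`conserved_occupancy`).  Gene extraction collects names of
genes overlapping any region extended by ±1000 bp (clipped at the
chromosome start), deduplicated; enrichment testing itself is out of
scope and the gene lists are exported for external tools.  The low-methyl
stratum is defined by the hi/low peak partition (β̄ ≤ 0.6), the only
self-consistent complement of the hi stratum.

## Synthetic data: what it emulates and what it does not

The generator produces the full input set with known truth:

* **Genome** — i.i.d. bases at a target GC (default 0.42) with evenly
  spaced CpG islands (default 150 × 2 kb) whose CG-dinucleotide rate is
  boosted by an enrichment factor (default 5×) over the background rate.
* **Methylome** — every CpG cytosine on both strands receives
  t ~ Poisson(depth/2) reads (so a merged unit averages `depth`, default
  30×) and m ~ Binomial(t, β) at the regime mean of its locus: background
  0.75 (a hypermethylated, stem-cell-flavoured genome), islands 0.05,
  peak and site-core regimes as planted.  Later regime intervals override
  earlier ones.  A two-replicate mode splits each locus's reads
  binomially/hypergeometrically, so merging the replicates reproduces the
  single-file totals exactly.  No bisulfite non-conversion error is
  simulated by default.
* **Peaks** — each planted peak contains exactly one occurrence sampled
  from its group's PWM (random strand) written into the genome; the peak
  interval is centered on the occurrence plus uniform jitter up to 25% of
  the width, so the recorded summit does not coincide with the site and
  relocation is genuinely exercised.  Noise peaks contain no occurrence.
  Placements use a non-overlapping slot grid that keeps every peak a full
  metaplot flank away from islands and neighbours, so each profile sees
  only its own planted regimes.
* **Study scenario** — two archetypes of 500 planted peaks + 25 noise
  peaks each.  The *methyl-preferring* TF (55% planned hi peaks): hi-group
  motif carries a CpG (consensus TTGACGTCAT, C·G probabilities 0.90/0.95),
  hi peaks at β 0.65 with a site core (±20 bp) at 0.95 — a center rise and
  E calls; its low-group variant mostly replaces the CpG's C with T.  The
  *methyl-avoiding* TF (30% planned hi peaks): hi peaks at β 0.90 with an
  unmethylated site core (±10 bp at 0.05, narrow so whole-peak means stay
  above the 0.6 cutoff) — a center dip and no E calls; its CpG-bearing
  variant appears only in the low group.  Consensus columns elsewhere use
  probability 0.95 (≈1.7 bits/column, a strong, well-defined motif: weak
  planted motifs make exact relocation information-theoretically
  impossible, which is a property of the motif, not the scanner).
  Segmentation covers each peak (±300 bp) with an enhancer label at rate
  0.8 (hi) / 0.3 (low), promoter otherwise, quiescent fill elsewhere.
  Six-cell occupancy plans give conserved rates 0.42/0.37 (hi/low) for
  the methyl-preferring TF and 0.19/0.67 for the methyl-avoiding one,
  realised as explicit boolean matrices with zero jitter by default.
  DNase peaks are split half on the methylated background, half inside
  islands, so the planned methylated-DHS fraction is 0.5.
* **Sizes** — 2 chromosomes × 2.6 Mb (~282k covered CpG units at 30×),
  chosen so a full simulation-plus-analysis runs in seconds while every
  estimated fraction keeps a standard error of ~2% or better.

What passing on this data does **not** show: the generator has no
chromatin-accessibility or nucleosome structure, no read-level ChIP-seq
noise (peaks are intervals, not called from reads), independent CpGs
within a regime (no spatial autocorrelation of β beyond the planted
blocks), and motif occurrences drawn i.i.d. from the PWM (no dinucleotide
or flanking-sequence dependence).  Results on real data additionally
depend on peak-calling quality, replicate concordance, and motif-model
mismatch, none of which are exercised here.

## Numerical choices and degenerate inputs

* PWM rows are validated to sum to 1 within 1e-9; zero-probability cells
  (possible only with pseudocount 0) yield −inf log-odds with a warning.
* Score ties in scanning break to the smaller offset, then the + strand;
  the brute-force comparisons in the tests accept either placement of an
  exact floating-point tie, since summation order can flip the argmax on
  the last bit.
* Undefined values (no coverage, no CpG, no overlap) propagate as NaN /
  `unassigned` / `no_cpg` and are excluded from fractions; functions
  whose denominator would be empty raise instead of returning NaN.
* Every random component (generators, discovery, bootstrap) takes an
  explicit seed and uses an isolated `numpy` Generator; reruns are
  byte-identical, a tested invariant.

## Known limitations

* Discovery is a single-motif ZOOPS model with hard assignments: co-factor
  motifs, multi-occurrence peaks and soft responsibilities are out of
  scope, and discovered score scales are not comparable across tools.
* The maximum rule for site methylation is deliberately one-sided; a
  mean- or count-weighted site level would behave differently for long
  sites with many CpGs.
* Peak-level means ignore CpG spacing; two peaks with identical means but
  opposite within-peak gradients are indistinguishable at this stage (the
  metaplot stage is where spatial structure appears).
* Conservation uses binary ≥1 bp overlap; fragmented peak calls in one
  cell type can inflate occupancy.
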