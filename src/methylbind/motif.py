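"""Position weight matrices: estimation, log-odds scoring, best-site
scanning, and a self-contained seeded discovery stage.

Scores are log2 odds against a mononucleotide background, in bits.  The
scanner returns the single maximum-scoring placement over every offset and
both strands of a peak sequence (the most likely binding site); ties break
deterministically to the smaller offset, then the + strand.  Placements
containing N are skipped rather than penalised.

Discovery is a ZOOPS-style hard EM: overrepresented k-mers versus a
shuffled background seed candidate matrices, each refined by alternating
best-site assignment and re-estimation until convergence; the candidate
with the best enrichment over shuffled sequences wins.  It is deterministic
given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """A, C, G, T -> 0..3; anything else -> -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def genome_background(genome: Dict[str, str]) -> np.ndarray:
    """Genome-wide mononucleotide frequencies over {A,C,G,T} (N ignored)."""
    counts = np.zeros(4, dtype=np.int64)
    for seq in genome.values():
        codes = encode(seq)
        counts += np.bincount(codes[codes >= 0], minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BACKGROUND.copy()
    return counts / counts.sum()


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix over {A,C,G,T} with background model."""

    probs: np.ndarray  # (L, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM must be an (L, 4) matrix")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if np.any(probs <= 0):
            logger.warning("PWM contains zero probabilities; scores may be -inf")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p / background) with -inf for zero probabilities."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def column_entropies(self) -> np.ndarray:
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return -terms.sum(axis=1)


@dataclass(frozen=True)
class ScanHit:
    """Best PWM placement within a scanned sequence."""

    offset: int  # 0-based offset of the site's leftmost base on the forward strand
    strand: str  # '+' or '-'
    score: float  # log-odds in bits


def build_pwm(
    aligned_sequences: Sequence[str],
    pseudocount: float = 0.5,
    background: Optional[np.ndarray] = None,
) -> Pwm:
    """Estimate a PWM from equal-length aligned sequences.

    Column probability of base b is ``(count_b + pseudocount) /
    (n + 4 * pseudocount)``; N-containing sequences are rejected.
    """
    if not aligned_sequences:
        raise ValueError("need at least one sequence")
    L = len(aligned_sequences[0])
    if any(len(s) != L for s in aligned_sequences):
        raise ValueError("aligned sequences must share one length")
    counts = np.zeros((L, 4), dtype=float)
    for s in aligned_sequences:
        codes = encode(s.upper())
        if np.any(codes < 0):
            raise ValueError(f"sequence contains non-ACGT characters: {s!r}")
        counts[np.arange(L), codes] += 1
    n = len(aligned_sequences)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    if pseudocount == 0 and np.any(counts == 0):
        logger.warning("zero pseudocount with unobserved bases yields degenerate PWM columns")
    bg = UNIFORM_BACKGROUND.copy() if background is None else background
    return Pwm(probs=probs, background=bg, pseudocount=pseudocount)


def score_site(pwm: Pwm, sequence: str) -> float:
    """Log-odds score (bits) of one placement; NaN if the sequence has N."""
    codes = encode(sequence.upper())
    if len(codes) != pwm.length:
        raise ValueError(f"sequence length {len(codes)} != PWM length {pwm.length}")
    if np.any(codes < 0):
        return float("nan")
    return float(pwm.log_odds[np.arange(pwm.length), codes].sum())


def _window_scores(pwm: Pwm, codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Forward and reverse scores for every offset; NaN where a window has N."""
    L = pwm.length
    n_off = len(codes) - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)[:n_off]
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    lo = pwm.log_odds
    idx = np.arange(L)
    fwd = lo[idx, safe].sum(axis=1)
    # reverse-complement placement: motif column j reads complement(window[L-1-j])
    rc_lo = lo[::-1, ::-1]
    rev = rc_lo[idx, safe].sum(axis=1)
    fwd = np.where(valid, fwd, np.nan)
    rev = np.where(valid, rev, np.nan)
    return fwd, rev


def scan_peak(pwm: Pwm, peak_sequence: str) -> ScanHit:
    """Maximum-scoring placement over all offsets and both strands.

    Deterministic tie-break: smaller offset first, then the + strand.
    Raises when the sequence is shorter than the PWM or no placement is
    free of N.
    """
    seq = peak_sequence.upper()
    if len(seq) < pwm.length:
        raise ValueError(f"sequence length {len(seq)} < PWM length {pwm.length}")
    fwd, rev = _window_scores(pwm, encode(seq))
    # offset-major, + before -: argmax returns the first maximum, which
    # realises the documented tie-break.
    both = np.stack([fwd, rev], axis=1).ravel()
    if np.all(np.isnan(both)):
        raise ValueError("no N-free placement in sequence")
    flat = int(np.nanargmax(both))
    offset, strand_i = divmod(flat, 2)
    return ScanHit(offset=offset, strand="+-"[strand_i], score=float(both[flat]))


@dataclass
class DiscoveryResult:
    """Outcome of de novo discovery: the motif plus its enrichment.

    ``enrichment`` is the mean best-site log-odds on the input sequences
    minus the same quantity on mononucleotide-shuffled sequences, so a
    motif that merely reflects base composition scores near zero.
    """

    pwm: Pwm
    enrichment: float
    width: int
    n_sequences: int

    @property
    def consensus(self) -> str:
        return self.pwm.consensus


def _shuffle_sequences(sequences: Sequence[str], rng: np.random.Generator) -> List[str]:
    out = []
    for s in sequences:
        chars = np.array(list(s))
        rng.shuffle(chars)
        out.append("".join(chars))
    return out


def _best_sites(pwm: Pwm, sequences: Sequence[str]) -> Tuple[List[str], float]:
    """Best-site sequence per scannable input (reverse-complemented for −
    hits) and the mean best score."""
    sites: List[str] = []
    scores: List[float] = []
    for s in sequences:
        if len(s) < pwm.length:
            continue
        try:
            hit = scan_peak(pwm, s)
        except ValueError:
            continue
        site = s[hit.offset : hit.offset + pwm.length].upper()
        if hit.strand == "-":
            site = reverse_complement(site)
        sites.append(site)
        scores.append(hit.score)
    mean = float(np.mean(scores)) if scores else float("-inf")
    return sites, mean


def _seed_kmers(
    sequences: Sequence[str], shuffled: Sequence[str], width: int, n_seeds: int
) -> List[str]:
    """Top k-mers by (count+1)/(shuffled count+1) enrichment, both strands."""

    def kmer_counts(seqs: Sequence[str]) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for s in seqs:
            s = s.upper()
            for i in range(len(s) - width + 1):
                k = s[i : i + width]
                if "N" in k:
                    continue
                canon = min(k, reverse_complement(k))
                counts[canon] = counts.get(canon, 0) + 1
        return counts

    fg = kmer_counts(sequences)
    bg = kmer_counts(shuffled)
    ranked = sorted(
        fg.items(),
        key=lambda kv: (-(kv[1] + 1) / (bg.get(kv[0], 0) + 1), kv[0]),
    )
    return [k for k, _ in ranked[:n_seeds]]


def _seed_pwm(kmer: str, background: np.ndarray) -> Pwm:
    L = len(kmer)
    probs = np.full((L, 4), 0.1)
    probs[np.arange(L), encode(kmer)] = 0.7
    return Pwm(probs=probs, background=background)


def discover_motif(
    sequences: Sequence[str],
    width_range: Tuple[int, int] = (8, 8),
    n_seeds: int = 8,
    seed: int = 0,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> DiscoveryResult:
    """Seeded de novo motif discovery, deterministic per seed.

    For each width, the most overrepresented k-mers (against a per-sequence
    mononucleotide shuffle) seed PWMs that are refined by alternating
    best-site assignment and PWM re-estimation until the maximum absolute
    probability change drops below ``tol`` (or ``max_iter`` rounds).  The
    final motif is the refined candidate with the highest enrichment.
    """
    w_min, w_max = width_range
    if w_min < 4:
        raise ValueError("motif width must be at least 4")
    if len(sequences) < 50:
        logger.warning("discovery on %d sequences; >=50 recommended", len(sequences))
    usable_max = max((len(s) for s in sequences), default=0)
    if usable_max < w_min:
        raise ValueError("all sequences shorter than the minimum motif width")

    rng = np.random.default_rng(seed)
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    shuffled = _shuffle_sequences(sequences, rng)

    best: Optional[DiscoveryResult] = None
    for width in range(w_min, w_max + 1):
        if usable_max < width:
            break
        for kmer in _seed_kmers(sequences, shuffled, width, n_seeds):
            pwm = _seed_pwm(kmer, bg)
            for _ in range(max_iter):
                sites, _ = _best_sites(pwm, sequences)
                if not sites:
                    break
                new = build_pwm(sites, pseudocount=pseudocount, background=bg)
                delta = float(np.max(np.abs(new.probs - pwm.probs)))
                pwm = new
                if delta < tol:
                    break
            _, fg_mean = _best_sites(pwm, sequences)
            _, bg_mean = _best_sites(pwm, shuffled)
            enrichment = fg_mean - bg_mean
            cand = DiscoveryResult(pwm=pwm, enrichment=enrichment, width=width, n_sequences=len(sequences))
            if best is None or cand.enrichment > best.enrichment:
                best = cand
    assert best is not None
    return best


def write_pwm(pwm: Pwm, path: Union[str, Path], as_counts_n: Optional[int] = None) -> None:
    """Write a JASPAR-style 4-row matrix (one row per base, tab-separated)."""
    mat = pwm.probs.T if as_counts_n is None else (pwm.probs.T * as_counts_n)
    with open(path, "w") as fh:
        for b, row in zip(ALPHABET, mat):
            fh.write(b + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_pwm(
    path: Union[str, Path],
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.5,
) -> Pwm:
    """Read a JASPAR-style 4-row matrix of counts or probabilities.

    Counts are converted to probabilities with the given pseudocount, so
    imported matrices never contain zero columns.
    """
    rows: Dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.replace("[", " ").replace("]", " ").split()
            if not fields:
                continue
            base = fields[0].upper()
            if base not in ALPHABET:
                raise ValueError(f"unexpected row label {fields[0]!r} in {path}")
            rows[base] = np.array([float(x) for x in fields[1:]])
    if sorted(rows) != list("ACGT"):
        raise ValueError(f"PWM file {path} must have exactly one row per base A/C/G/T")
    mat = np.stack([rows[b] for b in ALPHABET], axis=1)  # (L, 4)
    col_sums = mat.sum(axis=1, keepdims=True)
    if np.allclose(col_sums, 1.0, atol=1e-6):
        probs = mat
    else:
        probs = (mat + pseudocount) / (col_sums + 4 * pseudocount)
    bg = UNIFORM_BACKGROUND.copy() if background is None else background
    return Pwm(probs=probs, background=bg, pseudocount=pseudocount)
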