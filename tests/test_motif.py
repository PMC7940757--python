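"""PWM estimation, log-odds scoring, scanning and discovery."""

import numpy as np
import pytest

from methylbind.motif import (
    Pwm,
    build_pwm,
    discover_motif,
    read_pwm,
    reverse_complement,
    scan_peak,
    score_site,
    write_pwm,
)

ALPHABET = "ACGT"


def random_seq(rng, n, p=None):
    return "".join(ALPHABET[c] for c in rng.choice(4, size=n, p=p))


def random_pwm(rng, L):
    probs = rng.dirichlet(np.ones(4) * 2, size=L)
    return Pwm(probs=probs)


def brute_score(pwm, seq, off, strand):
    window = seq[off : off + pwm.length]
    if strand == "-":
        window = reverse_complement(window)
    return sum(
        float(np.log2(pwm.probs[j, ALPHABET.index(b)] / pwm.background[ALPHABET.index(b)]))
        for j, b in enumerate(window)
    )


def brute_scan(pwm, seq):
    """Exhaustive enumeration of every (offset, strand) placement."""
    best = None
    L = pwm.length
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        if "N" in window:
            continue
        for strand, s in (("+", window), ("-", reverse_complement(window))):
            score = sum(
                float(np.log2(pwm.probs[j, ALPHABET.index(b)] / pwm.background[ALPHABET.index(b)]))
                for j, b in enumerate(s)
            )
            key = (score, -off, strand == "+")  # mirror the documented tie-break
            if best is None or key > best[0]:
                best = (key, off, strand, score)
    return best[1], best[2], best[3]


class TestBuildPwm:
    def test_hand_counted_probabilities(self):
        pwm = build_pwm(["ACGT", "ACGT", "ACGA"], pseudocount=1)
        assert pwm.probs[3, ALPHABET.index("T")] == pytest.approx(3 / 7)
        assert pwm.probs[3, ALPHABET.index("A")] == pytest.approx(2 / 7)

    def test_zero_pseudocount_degenerate_allowed(self):
        pwm = build_pwm(["A"], pseudocount=0)
        assert pwm.probs[0, 0] == 1.0

    def test_pseudocount_floors_unobserved(self):
        pwm = build_pwm(["A", "A", "A"], pseudocount=1)
        assert pwm.probs[0, ALPHABET.index("C")] == pytest.approx(1 / 7)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["AC", "ACG"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["AN"])


class TestScoreSite:
    def test_uniform_pwm_scores_zero(self):
        pwm = Pwm(probs=np.full((6, 4), 0.25))
        assert score_site(pwm, "ACGTAC") == pytest.approx(0.0)

    def test_single_column_one_bit(self):
        pwm = Pwm(probs=np.array([[0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]]))
        assert score_site(pwm, "A") == pytest.approx(1.0)

    def test_n_gives_nan(self):
        pwm = Pwm(probs=np.full((2, 4), 0.25))
        assert np.isnan(score_site(pwm, "AN"))

    def test_matches_manual_sum(self):
        rng = np.random.default_rng(7)
        pwm = random_pwm(rng, 8)
        for _ in range(100):
            seq = random_seq(rng, 8)
            manual = sum(
                float(np.log2(pwm.probs[j, ALPHABET.index(b)] * 4)) for j, b in enumerate(seq)
            )
            assert score_site(pwm, seq) == pytest.approx(manual)


class TestScanPeak:
    def test_planted_consensus_found(self):
        rng = np.random.default_rng(8)
        pwm = Pwm(probs=np.where(np.eye(4)[[0, 1, 2, 3, 0, 1]] == 1, 0.91, 0.03))
        consensus = "ACGTAC"
        seq = random_seq(rng, 40) + consensus + random_seq(rng, 40)
        hit = scan_peak(pwm, seq)
        assert (hit.offset, hit.strand) == (40, "+")

    def test_exhaustive_equivalence(self):
        rng = np.random.default_rng(9)
        for _ in range(150):
            L = int(rng.integers(4, 9))
            pwm = random_pwm(rng, L)
            seq = random_seq(rng, int(rng.integers(L, 60)))
            hit = scan_peak(pwm, seq)
            off, strand, score = brute_scan(pwm, seq)
            assert hit.score == pytest.approx(score)
            if (hit.offset, hit.strand) != (off, strand):
                # distinct placements may tie to the last bit; the scanner
                # then legitimately returns either one
                alt = brute_score(pwm, seq, hit.offset, hit.strand)
                assert alt == pytest.approx(score)

    def test_reverse_complement_flips_strand_keeps_score(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            pwm = random_pwm(rng, 6)
            seq = random_seq(rng, 30)
            a = scan_peak(pwm, seq)
            b = scan_peak(pwm, reverse_complement(seq))
            assert a.score == pytest.approx(b.score)

    def test_palindrome_tie_breaks_to_plus(self):
        pwm = Pwm(probs=np.full((4, 4), 0.25))
        hit = scan_peak(pwm, "ACGT")
        assert hit.strand == "+" and hit.offset == 0

    def test_flank_never_lowers_best_score(self):
        rng = np.random.default_rng(11)
        pwm = random_pwm(rng, 6)
        seq = random_seq(rng, 30)
        base = scan_peak(pwm, seq).score
        assert scan_peak(pwm, "A" * 10 + seq + "A" * 10).score >= base - 1e-12

    def test_short_peak_rejected(self):
        pwm = Pwm(probs=np.full((6, 4), 0.25))
        with pytest.raises(ValueError):
            scan_peak(pwm, "ACG")

    def test_all_n_rejected(self):
        pwm = Pwm(probs=np.full((3, 4), 0.25))
        with pytest.raises(ValueError):
            scan_peak(pwm, "NNNNN")


def planted_sequences(rng, probs, n=120, length=120):
    seqs = []
    for _ in range(n):
        s = random_seq(rng, length)
        site = "".join(ALPHABET[rng.choice(4, p=probs[j])] for j in range(len(probs)))
        if rng.random() < 0.5:
            site = reverse_complement(site)
        off = int(rng.integers(0, length - len(probs) + 1))
        seqs.append(s[:off] + site + s[off + len(probs) :])
    return seqs


class TestDiscovery:
    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(12)
        probs = np.where(np.eye(4)[[3, 2, 0, 1, 2, 3]] == 1, 0.88, 0.04)
        seqs = planted_sequences(rng, probs, n=80, length=80)
        a = discover_motif(seqs, width_range=(6, 6), n_seeds=4, seed=5)
        b = discover_motif(seqs, width_range=(6, 6), n_seeds=4, seed=5)
        assert np.array_equal(a.pwm.probs, b.pwm.probs)
        assert a.enrichment == b.enrichment

    def test_planted_motif_enriched_over_random(self):
        rng = np.random.default_rng(13)
        probs = np.where(np.eye(4)[[3, 2, 0, 1, 2, 3]] == 1, 0.88, 0.04)
        planted = discover_motif(
            planted_sequences(rng, probs, n=80, length=80), width_range=(6, 6), n_seeds=4, seed=1
        )
        rand = discover_motif(
            [random_seq(rng, 80) for _ in range(80)], width_range=(6, 6), n_seeds=4, seed=1
        )
        assert planted.enrichment >= 2 * rand.enrichment

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            discover_motif(["ACGT"], width_range=(6, 6))


class TestPwmFiles:
    def test_probability_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        pwm = random_pwm(rng, 7)
        path = tmp_path / "m.txt"
        write_pwm(pwm, path)
        back = read_pwm(path)
        assert np.allclose(back.probs, pwm.probs, atol=1e-5)

    def test_count_matrix_converted_with_pseudocount(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("A\t8\nC\t0\nG\t0\nT\t2\n")
        pwm = read_pwm(path, pseudocount=0.5)
        assert pwm.probs[0, 0] == pytest.approx(8.5 / 12)
        assert np.all(pwm.probs > 0)
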