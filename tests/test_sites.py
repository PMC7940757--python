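"""Binding-site relocation, site-level methylation and E-alphabet motifs."""

import math

import numpy as np
import pytest

from methylbind.io import Peak
from methylbind.peaks import PipelineThresholds
from methylbind.sites import (
    BindingSite,
    MethylMotif,
    annotate_e_sequence,
    cpg_site_fraction,
    group_site,
    locate_binding_sites,
    rebuild_methyl_motif,
    site_methylation,
)

from conftest import make_track


def site_at(chrom, start, seq, strand="+", peak=None):
    peak = peak or Peak(chrom, max(start - 20, 0), start + len(seq) + 20, name="p")
    return BindingSite(peak=peak, start=start, strand=strand, score=0.0, sequence=seq)


class TestSiteMethylation:
    def test_maximum_of_overlapping_cpgs(self):
        track = make_track([("chr1", 102, 3, 10), ("chr1", 106, 8, 10)])
        site = site_at("chr1", 100, "ACGTACGTAC")
        assert site_methylation(site, track) == pytest.approx(0.8)

    def test_single_cpg(self):
        track = make_track([("chr1", 104, 5, 10)])
        assert site_methylation(site_at("chr1", 100, "ACGTACGT"), track) == pytest.approx(0.5)

    def test_no_cpg_undefined(self):
        track = make_track([("chr1", 500, 5, 10)])
        assert math.isnan(site_methylation(site_at("chr1", 100, "ACGTACGT"), track))

    def test_unit_overlapping_left_edge_counts(self):
        # merged CpG unit at 99 spans [99, 101) and so overlaps a site starting at 100
        track = make_track([("chr1", 99, 9, 10)])
        assert site_methylation(site_at("chr1", 100, "GTACGTAC"), track) == pytest.approx(0.9)


class TestGroupSite:
    @pytest.mark.parametrize(
        "level,expected",
        [(0.7, "high"), (0.1, "low"), (0.4, "middle"), (0.6, "middle"), (0.2, "middle")],
    )
    def test_strict_boundaries(self, level, expected):
        assert group_site(level) == expected

    def test_undefined_is_no_cpg(self):
        assert group_site(float("nan")) == "no_cpg"


class TestCpgSiteFraction:
    def test_substring_rule(self):
        sites = [site_at("chr1", 0, s) for s in ["ACGT", "AAAA", "TTCG", "GGGG"]]
        assert cpg_site_fraction(sites) == pytest.approx(0.5)

    def test_all_cpg_free(self):
        assert cpg_site_fraction([site_at("chr1", 0, "ATAT")]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cpg_site_fraction([])

    def test_matches_substring_count_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(30):
            seqs = ["".join("ACGT"[c] for c in rng.choice(4, 8)) for _ in range(20)]
            sites = [site_at("chr1", 0, s) for s in seqs]
            assert cpg_site_fraction(sites) == pytest.approx(
                sum("CG" in s for s in seqs) / len(seqs)
            )


class TestEAnnotation:
    GENOME = {"chr1": "TACGTTTT"}  # CpG at 2-3

    def test_methylated_cpg_becomes_e_on_plus(self):
        track = make_track([("chr1", 2, 9, 10)])
        site = site_at("chr1", 1, "ACGT")
        assert annotate_e_sequence(site, track, self.GENOME, 0.6) == "AEGT"

    def test_low_methylation_stays_c(self):
        track = make_track([("chr1", 2, 3, 10)])
        site = site_at("chr1", 1, "ACGT")
        assert annotate_e_sequence(site, track, self.GENOME, 0.6) == "ACGT"

    def test_non_cpg_c_never_e(self):
        genome = {"chr1": "TACATTTT"}  # C at 2 not followed by G
        track = make_track([("chr1", 2, 9, 10)])
        site = site_at("chr1", 1, "ACAT")
        assert annotate_e_sequence(site, track, genome, 0.6) == "ACAT"

    def test_minus_strand_reads_merged_unit(self):
        # site covers genomic ACGTA at 1..6 on the minus strand;
        # reading sequence is TACGT with its C at reading position 2,
        # whose CpG unit is the + strand C at genomic position 2
        genome = {"chr1": "TACGTATT"}
        track = make_track([("chr1", 2, 9, 10)])
        site = site_at("chr1", 1, "ACGTA", strand="-")
        assert site.reading_sequence == "TACGT"
        assert annotate_e_sequence(site, track, genome, 0.6) == "TAEGT"

    def test_minus_strand_oracle_random_cases(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            seq = "".join("ACGT"[c] for c in rng.choice(4, 30))
            genome = {"chr1": seq}
            units = [
                ("chr1", p, 9 if rng.random() < 0.5 else 1, 10)
                for p in range(29)
                if seq[p : p + 2] == "CG"
            ]
            if not units:
                continue
            track = make_track(units)
            start = int(rng.integers(0, 20))
            site = site_at("chr1", start, seq[start : start + 10], strand="-")
            annotated = annotate_e_sequence(site, track, genome, 0.6)
            # oracle: walk the genomic window, mark methylated CpG Cs, then
            # reverse-complement with E pairing to E
            levels = {p: m / t for _, p, m, t in units}
            marked = []
            window = seq[start : start + 10]
            for j, b in enumerate(window):
                g = start + j
                if b == "G" and seq[g - 1 : g + 1] == "CG" and levels.get(g - 1, 0) > 0.6:
                    marked.append("e")  # minus-strand methylated C pairs with this G
                else:
                    marked.append(b)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A", "e": "E"}
            expected = "".join(comp[b] for b in reversed(marked))
            assert annotated == expected


class TestRebuildMethylMotif:
    def test_counts_and_collapse(self):
        genome = {"chr1": "TACGTTTT"}
        track = make_track([("chr1", 2, 9, 10)])
        sites = [site_at("chr1", 1, "ACGT") for _ in range(3)]
        motif = rebuild_methyl_motif(sites, track, genome, e_threshold=0.6)
        assert motif.counts[1, 4] == 3  # E at the C column
        assert motif.counts[1, 1] == 0
        collapsed = motif.collapse_to_acgt()
        assert collapsed[1, 1] == 3  # E folds back onto C
        assert motif.e_fraction(1) == 1.0

    def test_mixed_lengths_rejected(self):
        genome = {"chr1": "TACGTTTT"}
        track = make_track([("chr1", 2, 9, 10)])
        with pytest.raises(ValueError):
            rebuild_methyl_motif(
                [site_at("chr1", 1, "ACGT"), site_at("chr1", 1, "ACG")], track, genome
            )


class TestLocateBindingSites:
    def test_planted_site_recovered_and_sequence_round_trips(self):
        from methylbind.motif import Pwm

        rng = np.random.default_rng(22)
        seq = "".join("ACGT"[c] for c in rng.choice(4, 400))
        consensus = "TTGACGTCAT"
        genome = {"chr1": seq[:150] + consensus + seq[160:]}
        probs = np.full((10, 4), 0.05 / 3 * 3)
        probs[:] = (1 - 0.9) / 3
        for j, b in enumerate(consensus):
            probs[j, "ACGT".index(b)] = 0.9
        pwm = Pwm(probs=probs)
        peak = Peak("chr1", 100, 300, name="pk")
        located = locate_binding_sites([peak], [], pwm, pwm, genome)
        (site,) = located["hi"]
        assert site.start == 150
        assert site.sequence == genome["chr1"][site.start : site.end]

    def test_overlapping_groups_rejected(self):
        from methylbind.motif import Pwm

        pwm = Pwm(probs=np.full((4, 4), 0.25))
        peak = Peak("chr1", 0, 50)
        with pytest.raises(ValueError):
            locate_binding_sites([peak], [peak], pwm, pwm, {"chr1": "A" * 60})

    def test_unscannable_peak_skipped(self):
        from methylbind.motif import Pwm

        pwm = Pwm(probs=np.full((4, 4), 0.25))
        genome = {"chr1": "N" * 100}
        located = locate_binding_sites([Peak("chr1", 0, 50)], [], pwm, pwm, genome)
        assert located["hi"] == []
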