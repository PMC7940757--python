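"""Generator properties: determinism, planted truth consistency, sampling."""

import numpy as np
import pytest

from methylbind.io import Peak
from methylbind.methylome import build_track, merge_replicates
from methylbind.motif import Pwm
from methylbind.synthetic import (
    SlotAllocator,
    cpg_positions,
    make_genome,
    make_methylome,
    make_multicell,
    make_segmentation,
    plant_peaks,
)


def strong_pwm(consensus="TTGACGTCAT", p=0.94):
    probs = np.full((len(consensus), 4), (1 - p) / 3)
    for j, b in enumerate(consensus):
        probs[j, "ACGT".index(b)] = p
    return Pwm(probs=probs)


class TestMakeGenome:
    def test_deterministic(self):
        a, _ = make_genome(seed=3, n_chroms=1, chrom_length=20000)
        b, _ = make_genome(seed=3, n_chroms=1, chrom_length=20000)
        assert a == b

    def test_island_cpg_density_exceeds_background(self):
        genome, islands = make_genome(
            seed=4, n_chroms=1, chrom_length=100000, island_spec=(5, 2000, 5.0)
        )
        seq = genome["chr1"]

        def cg_density(s):
            return sum(1 for i in range(len(s) - 1) if s[i : i + 2] == "CG") / len(s)

        island_seq = "".join(seq[s:e] for _, s, e in islands)
        rest = seq[: islands[0][1]]
        assert cg_density(island_seq) > 2 * cg_density(rest)

    def test_gc_zero_gives_at_only(self):
        genome, _ = make_genome(seed=5, n_chroms=1, chrom_length=20000, gc=0.0, island_spec=(0, 0, 1))
        assert set(genome["chr1"]) <= {"A", "T"}

    def test_oversized_islands_rejected(self):
        with pytest.raises(ValueError):
            make_genome(seed=6, n_chroms=1, chrom_length=10000, island_spec=(2, 9000, 2.0))


class TestMakeMethylome:
    def _genome(self):
        genome, _ = make_genome(seed=7, n_chroms=1, chrom_length=50000)
        return genome

    def test_regime_mean_one_gives_full_methylation(self):
        genome = self._genome()
        (records,) = make_methylome(genome, [("chr1", 0, 50000, 1.0)], depth=30, seed=1)
        covered = [r for r in records if r.total_reads > 0]
        assert covered and all(r.meth_reads == r.total_reads for r in covered)

    def test_pooled_level_matches_regime_within_3se(self):
        genome = self._genome()
        m = 0.7
        (records,) = make_methylome(genome, [("chr1", 0, 50000, m)], depth=30, seed=2)
        meth = sum(r.meth_reads for r in records)
        total = sum(r.total_reads for r in records)
        se = np.sqrt(m * (1 - m) / total)
        assert abs(meth / total - m) < 3 * se

    def test_replicate_split_merges_back_exactly(self):
        genome = self._genome()
        regimes = [("chr1", 0, 50000, 0.4)]
        (single,) = make_methylome(genome, regimes, depth=20, seed=3)
        rep_a, rep_b = make_methylome(genome, regimes, depth=20, seed=3, replicates=2)
        merged = merge_replicates(rep_a, rep_b)
        assert merged == sorted(single, key=lambda r: (r.chrom, r.pos, r.strand))

    def test_both_strands_emitted_per_cpg(self):
        genome = self._genome()
        (records,) = make_methylome(genome, [], depth=10, seed=4)
        n_cpg = sum(len(v) for v in cpg_positions(genome).values())
        assert len(records) == 2 * n_cpg

    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError):
            make_methylome(self._genome(), [("chr1", 0, 10, 1.5)])


class TestPlantPeaks:
    def test_truth_count_and_containment(self):
        genome, _ = make_genome(seed=8, n_chroms=1, chrom_length=200000, island_spec=(0, 0, 1))
        res = plant_peaks(genome, strong_pwm(), n_sites=20, n_noise_peaks=5, seed=1)
        assert len(res.sites) == 20 and len(res.peaks) == 25
        for site, peak in zip(res.sites, res.peaks):
            assert peak.start <= site.start and site.start + 10 <= peak.end

    def test_occurrence_written_into_genome(self):
        genome, _ = make_genome(seed=9, n_chroms=1, chrom_length=200000, island_spec=(0, 0, 1))
        pwm = strong_pwm(p=0.999)  # essentially always the consensus
        res = plant_peaks(genome, pwm, n_sites=10, seed=2)
        from methylbind.motif import reverse_complement

        for site in res.sites:
            written = res.genome[site.chrom][site.start : site.start + 10]
            if site.strand == "-":
                written = reverse_complement(written)
            assert written == "TTGACGTCAT"

    def test_too_many_sites_rejected(self):
        genome, _ = make_genome(seed=10, n_chroms=1, chrom_length=20000, island_spec=(0, 0, 1))
        with pytest.raises(ValueError):
            plant_peaks(genome, strong_pwm(), n_sites=10000, seed=0)


class TestMulticell:
    def _peaks(self, n=10):
        return [Peak("chr1", i * 1000, i * 1000 + 200, name=f"p{i}") for i in range(n)]

    def test_all_ones_plan_occupies_everywhere(self):
        peaks = self._peaks()
        plan = np.ones((10, 6), dtype=bool)
        res = make_multicell(peaks, 6, plan, seed=0)
        assert all(len(c) == 10 for c in res.cell_peaks)

    def test_explicit_plan_realised_exactly(self):
        peaks = self._peaks(4)
        plan = np.zeros((4, 3), dtype=bool)
        plan[:, 0] = True
        plan[0, 1] = plan[2, 2] = True
        res = make_multicell(peaks, 3, plan, seed=1)
        assert [p.name.split("_cell")[0] for p in res.cell_peaks[0]] == ["p0"]
        assert [p.name.split("_cell")[0] for p in res.cell_peaks[1]] == ["p2"]

    def test_reference_column_must_be_true(self):
        plan = np.zeros((2, 3), dtype=bool)
        with pytest.raises(ValueError, match="reference"):
            make_multicell(self._peaks(2), 3, plan)

    def test_excessive_jitter_rejected(self):
        plan = np.ones((2, 3), dtype=bool)
        with pytest.raises(ValueError, match="jitter"):
            make_multicell(self._peaks(2), 3, plan, jitter=500)


class TestSegmentation:
    def test_labels_cover_peaks_and_fill_gaps(self):
        peaks = [Peak("chr1", 1000 * i + 100, 1000 * i + 300, name=f"p{i}") for i in range(5)]
        segments, truth = make_segmentation(
            peaks, ["hi"] * 5, {"chr1": 10000}, enhancer_rate_hi=1.0, seed=0
        )
        assert set(truth.values()) == {"7_Enhancer"}
        covered = sum(s.end - s.start for s in segments)
        assert covered == 10000  # tiles the chromosome


class TestSlotAllocator:
    def test_slots_disjoint_and_respect_exclusions(self):
        rng = np.random.default_rng(60)
        alloc = SlotAllocator({"chr1": 100000}, spacing=1000, margin=100,
                              exclude=[("chr1", 40000, 45000)])
        slots = alloc.take(50, rng)
        starts = sorted(s for _, s in slots)
        assert all(b - a >= 1000 for a, b in zip(starts, starts[1:]))
        assert all(not (39900 <= s < 45100) for s in starts)

    def test_exhaustion_rejected(self):
        rng = np.random.default_rng(61)
        alloc = SlotAllocator({"chr1": 20000}, spacing=1000)
        with pytest.raises(ValueError):
            alloc.take(1000, rng)
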