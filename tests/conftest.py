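import numpy as np
import pytest

from methylbind.io import CytosineRecord, Peak
from methylbind.methylome import MethylomeTrack, build_track


def make_track(units, cpg_unit=True):
    """Build a MethylomeTrack directly from (chrom, pos, meth, total) tuples."""
    by_chrom = {}
    for chrom, pos, meth, total in units:
        by_chrom.setdefault(chrom, []).append((pos, meth, total))
    positions, meths, totals = {}, {}, {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        positions[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
        meths[chrom] = np.array([r[1] for r in rows], dtype=np.int64)
        totals[chrom] = np.array([r[2] for r in rows], dtype=np.int64)
    return MethylomeTrack(positions=positions, meth=meths, total=totals, cpg_unit=cpg_unit)


def random_track(rng, chrom="chr1", n=40, span=2000, cpg_unit=True):
    pos = np.sort(rng.choice(span, size=n, replace=False))
    total = rng.poisson(20, size=n) + 1
    meth = rng.binomial(total, rng.random(n))
    return make_track([(chrom, int(p), int(m), int(t)) for p, m, t in zip(pos, meth, total)], cpg_unit)


@pytest.fixture(scope="session")
def small_study():
    """A reduced paper-shaped study shared by scenario-level tests."""
    from methylbind.scenario import simulate_study

    return simulate_study(
        seed=11, n_peaks_per_tf=100, n_noise=10, chrom_length=1_000_000, n_dhs_per_regime=40
    )


@pytest.fixture(scope="session")
def small_analysis(small_study):
    from methylbind.scenario import analyze_study

    return analyze_study(small_study)
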