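"""Methylation metaplots around binding-site centers.

Every CpG unit within ±flank (default 1600 bp) of a site's center
contributes its level to the bin of its signed offset; − strand sites have
offsets negated so profiles are oriented 5'->3' on the binding strand.
Each CpG contributes once per overlapping site window, so windows that
share CpGs intentionally double-count them, as metaplots conventionally
do.  Per-bin means are over contributions; bins with no contribution have
undefined (NaN) means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .methylome import MethylomeTrack
from .sites import BindingSite


@dataclass
class MethylationProfile:
    """Binned mean methylation by signed offset from the site center."""

    bin_width: int
    offsets: np.ndarray  # bin centers, symmetric about 0
    mean_level: np.ndarray  # NaN where n_cpg == 0
    n_cpg: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.offsets)


def _site_bin_sums(
    sites: Sequence[BindingSite],
    track: MethylomeTrack,
    flank: int,
    bin_width: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_sites, n_bins) level sums and counts, plus bin centers."""
    n_bins = (2 * flank) // bin_width
    if n_bins * bin_width != 2 * flank:
        raise ValueError("bin width must divide 2*flank")
    sums = np.zeros((len(sites), n_bins))
    counts = np.zeros((len(sites), n_bins), dtype=np.int64)
    for i, site in enumerate(sites):
        center = site.center
        pos, levels = track.query_interval(
            site.peak.chrom, max(center - flank, 0), center + flank
        )
        if len(pos) == 0:
            continue
        off = pos - center
        if site.strand == "-":
            off = -off
        keep = (off >= -flank) & (off < flank)
        off, levels = off[keep], levels[keep]
        bins = (off + flank) // bin_width
        np.add.at(sums[i], bins, levels)
        np.add.at(counts[i], bins, 1)
    centers = -flank + (np.arange(n_bins) + 0.5) * bin_width
    return sums, counts, centers


def flank_profile(
    sites: Sequence[BindingSite],
    track: MethylomeTrack,
    flank: int = 1600,
    bin_width: int = 25,
) -> MethylationProfile:
    """Aggregate methylation around site centers into a metaplot."""
    if not sites:
        raise ValueError("no binding sites")
    sums, counts, centers = _site_bin_sums(sites, track, flank, bin_width)
    tot_counts = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(tot_counts > 0, sums.sum(axis=0) / np.maximum(tot_counts, 1), np.nan)
    return MethylationProfile(
        bin_width=bin_width, offsets=centers, mean_level=means, n_cpg=tot_counts
    )


def profile_difference(
    profile_hi: MethylationProfile, profile_low: MethylationProfile
) -> np.ndarray:
    """Per-bin hi − low difference; binning must match exactly."""
    if profile_hi.bin_width != profile_low.bin_width or not np.array_equal(
        profile_hi.offsets, profile_low.offsets
    ):
        raise ValueError("profile binnings do not match")
    return profile_hi.mean_level - profile_low.mean_level


@dataclass
class ProfileContrast:
    """hi − low metaplot difference with bootstrap confidence bands."""

    offsets: np.ndarray
    difference: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_resamples: int


def profile_contrast(
    sites_hi: Sequence[BindingSite],
    sites_low: Sequence[BindingSite],
    track: MethylomeTrack,
    flank: int = 1600,
    bin_width: int = 25,
    n_resamples: int = 200,
    seed: int = 0,
) -> ProfileContrast:
    """Per-bin hi − low difference with 95% bands by resampling sites.

    Both groups are profiled with identical binning; each bootstrap
    replicate resamples sites with replacement within each group.
    """
    if not sites_hi or not sites_low:
        raise ValueError("both site groups must be non-empty")
    sums_h, cnt_h, centers = _site_bin_sums(sites_hi, track, flank, bin_width)
    sums_l, cnt_l, _ = _site_bin_sums(sites_low, track, flank, bin_width)

    def group_mean(sums: np.ndarray, cnt: np.ndarray, idx: Optional[np.ndarray]) -> np.ndarray:
        if idx is not None:
            sums, cnt = sums[idx], cnt[idx]
        tot = cnt.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, sums.sum(axis=0) / np.maximum(tot, 1), np.nan)

    diff = group_mean(sums_h, cnt_h, None) - group_mean(sums_l, cnt_l, None)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_resamples, len(centers)))
    for b in range(n_resamples):
        ih = rng.integers(0, len(sites_hi), len(sites_hi))
        il = rng.integers(0, len(sites_low), len(sites_low))
        boots[b] = group_mean(sums_h, cnt_h, ih) - group_mean(sums_l, cnt_l, il)
    band_low = np.nanpercentile(boots, 2.5, axis=0)
    band_high = np.nanpercentile(boots, 97.5, axis=0)
    return ProfileContrast(
        offsets=centers,
        difference=diff,
        band_low=band_low,
        band_high=band_high,
        n_resamples=n_resamples,
    )
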