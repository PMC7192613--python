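"""Comparison views: 50-nt binned size distributions and lane-fraction profiles.

Two normalized views support between-strain comparisons: per-Gb fragment
counts summed into 50-nt size bins and normalized to unit total (with bins
below the lane's detection limit dropped first), and within-lane
fraction-normalized densitometry profiles for strand-specific Southern
comparisons. Because detection limits (sz_min) differ between gels, cross-gel
comparisons are restricted to the bins above the largest sz_min involved and
renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .profiles import IntensityProfile
from .quantitation import FragmentCountTable

__all__ = [
    "BinnedSizeDistribution",
    "bin_distribution",
    "restrict_common_support",
    "lane_fraction_profile",
    "plot_distributions",
]


@dataclass
class BinnedSizeDistribution:
    """Fragment-size distribution in fixed-width (default 50 nt) bins.

    ``fractions`` sum to 1 over the reported bins; ``counts_per_gb`` keeps the
    unnormalized per-Gb counts for count-scale renderings. No reported bin
    starts below ``sz_min``.
    """

    edges: np.ndarray             # bin edges, nt; len(fractions) + 1
    fractions: np.ndarray
    counts_per_gb: np.ndarray
    sz_min: float
    lane_id: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def lo(self) -> np.ndarray:
        return self.edges[:-1]

    @property
    def hi(self) -> np.ndarray:
        return self.edges[1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_lo_nt": self.lo, "bin_hi_nt": self.hi,
                             "fraction": self.fractions,
                             "count_per_gb": self.counts_per_gb})


def bin_distribution(table: FragmentCountTable, bin_width: float = 50.0) -> BinnedSizeDistribution:
    """Sum per-Gb counts into half-open [k·w, (k+1)·w) size bins, normalize to 1.

    Bins whose lower edge lies below the lane's sz_min are dropped before
    normalization (a bin is reported only if it lies entirely above the
    detection limit).
    """
    if table.per_gb is None:
        raise ValueError("bin_distribution needs a per-Gb-normalized table")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    inc = table.included
    sizes = table.size[inc]
    counts = table.per_gb[inc]
    if sizes.size == 0 or np.sum(counts) <= 0:
        raise ValueError("empty table: no included intervals with counts")
    sz_min = table.sz_min if table.sz_min is not None else 0.0
    k0 = int(np.ceil(sz_min / bin_width - 1e-9))
    k = np.floor(sizes / bin_width).astype(int)
    keep = k >= k0
    if not np.any(keep):
        raise ValueError("no bins above sz_min")
    k_max = int(k[keep].max())
    n_bins = k_max - k0 + 1
    binned = np.zeros(n_bins)
    np.add.at(binned, k[keep] - k0, counts[keep])
    total = binned.sum()
    if total <= 0:
        raise ValueError("no counts above sz_min")
    edges = bin_width * np.arange(k0, k_max + 2)
    return BinnedSizeDistribution(edges=edges, fractions=binned / total,
                                  counts_per_gb=binned, sz_min=float(sz_min),
                                  lane_id=table.lane_id, metadata=dict(table.metadata))


def restrict_common_support(dists: list[BinnedSizeDistribution]) -> list[BinnedSizeDistribution]:
    """Truncate all distributions to bins above the largest sz_min, renormalize.

    Idempotent; raises if the common support is empty.
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 distributions to restrict support")
    sz_floor = max(d.sz_min for d in dists)
    out = []
    for dist in dists:
        keep = dist.lo >= sz_floor - 1e-9
        if not np.any(keep):
            raise ValueError(f"lane {dist.lane_id}: empty support above {sz_floor:g} nt")
        fractions = dist.fractions[keep]
        total = fractions.sum()
        if total <= 0:
            raise ValueError(f"lane {dist.lane_id}: zero mass above {sz_floor:g} nt")
        edges = np.concatenate([dist.lo[keep], [dist.hi[keep][-1]]])
        out.append(dc_replace(dist, edges=edges, fractions=fractions / total,
                              counts_per_gb=dist.counts_per_gb[keep], sz_min=sz_floor))
    return out


def lane_fraction_profile(profile: IntensityProfile) -> IntensityProfile:
    """Normalize each sample to the within-lane intensity sum (sums to 1).

    The Southern-comparison view: loading-independent per-lane fractions.
    Expects a background-subtracted profile.
    """
    total = float(np.sum(profile.intensities))
    if total <= 0:
        raise ValueError(f"lane {profile.lane_id}: zero-sum profile cannot be normalized")
    return profile.replace(profile.intensities / total, normalization="lane_fraction")


def plot_distributions(dists, path, per_gb: bool = False, title: str | None = None):
    """Overlay step plot of binned distributions on a log size axis (SVG/PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for dist in dists:
        y = dist.counts_per_gb if per_gb else dist.fractions
        ax.step(dist.lo, y, where="post", label=dist.lane_id or None)
    ax.set_xscale("log")
    ax.set_xlabel("fragment size (nt)")
    ax.set_ylabel("fragments per Gb" if per_gb else "fraction of fragments")
    if title:
        ax.set_title(title)
    if any(d.lane_id for d in dists):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
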