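"""Radial profile container shared by the simulation and quantification layers.

A :class:`RadialProfile` is a binned statistic over dimensionless radius
R = distance-to-centroid / island radius.  It is the common output surface of
the Notch lattice simulations, the traction maps and the per-cell
quantification, which makes simulated and measured profiles directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RadialProfile"]


@dataclass
class RadialProfile:
    """A per-bin statistic over dimensionless radius.

    Parameters
    ----------
    bin_edges
        Monotone array of ``n_bins + 1`` edges partitioning the radial range.
    values
        Per-bin statistic (mean, count, percent or density); ``NaN`` marks an
        empty bin — empty bins are *missing*, never zero.
    counts
        Number of observations per bin.
    ci_low, ci_high
        Optional pointwise 95% confidence bounds.
    statistic
        Label of the binned quantity (e.g. ``"mean_traction_pa"``).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    statistic: str = "mean"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 3:
            raise ValueError("bin_edges must be 1-D with at least 2 bins")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.values.shape != (self.n_bins,):
            raise ValueError("values length must equal number of bins")
        if self.counts.shape != (self.n_bins,):
            raise ValueError("counts length must equal number of bins")

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def nonempty(self) -> np.ndarray:
        """Boolean mask of bins holding at least one observation."""
        return np.asarray(self.counts) > 0

    def to_frame(self):
        """Tidy :class:`pandas.DataFrame` view (one row per bin)."""
        import pandas as pd

        data = {
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "radius_mid": self.centers,
            self.statistic: self.values,
            "n": self.counts,
        }
        if self.ci_low is not None:
            data["ci_low"] = self.ci_low
            data["ci_high"] = self.ci_high
        return pd.DataFrame(data)


def bin_mean_profile(
    radius: np.ndarray,
    values: np.ndarray,
    bin_edges: np.ndarray,
    statistic: str = "mean",
    with_ci: bool = False,
) -> RadialProfile:
    """Mean of ``values`` per radial bin; NaN in empty bins.

    The rightmost edge is inclusive (``numpy.histogram`` convention) so a
    point at exactly the outer radius lands in the last bin.
    """
    radius = np.asarray(radius, dtype=float)
    values = np.asarray(values, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    n_bins = bin_edges.size - 1
    idx = np.digitize(radius, bin_edges) - 1
    idx[radius == bin_edges[-1]] = n_bins - 1
    inside = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[inside], minlength=n_bins)
    sums = np.bincount(idx[inside], weights=values[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ci_low = ci_high = None
    if with_ci:
        sq = np.bincount(idx[inside], weights=values[inside] ** 2, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            var = np.where(counts > 1, (sq - counts * means**2) / np.maximum(counts - 1, 1), np.nan)
            sem = np.sqrt(var / np.maximum(counts, 1))
        ci_low = means - 1.96 * sem
        ci_high = means + 1.96 * sem
    return RadialProfile(bin_edges, means, counts, ci_low, ci_high, statistic=statistic)
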