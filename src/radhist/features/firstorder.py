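"""First-order (intensity histogram) statistics of the masked voxels.

Fifteen statistics are computed: the fourteen classic descriptive statistics
plus total energy (energy scaled by the physical voxel volume).  Variance,
standard deviation and the higher moments use the population convention
(divide by n).  Entropy and uniformity are computed from an equal-width
histogram between the masked minimum and maximum (``n_bins`` bins, log base
2); a constant region occupies a single bin, so entropy is 0 and uniformity 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["first_order_stats", "FIRST_ORDER_NAMES"]

FIRST_ORDER_NAMES = (
    "energy", "total_energy", "entropy", "minimum", "maximum", "mean",
    "median", "range", "mean_absolute_deviation", "root_mean_square",
    "skewness", "kurtosis", "standard_deviation", "uniformity", "variance",
)


def _histogram_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.array([1.0])
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    return counts[counts > 0] / x.size


def first_order_stats(masked_intensities, n_bins: int = 32,
                      voxel_volume: float = 1.0) -> dict[str, float]:
    """The 15 first-order features of a flat list of masked intensities.

    ``voxel_volume`` (mm^3) only enters ``total_energy``.  Skewness and
    kurtosis are the population moment ratios m3/m2^1.5 and m4/m2^2 (kurtosis
    is not excess-corrected: a Gaussian gives ~3); both are defined as 0 for
    a constant input.
    """
    x = np.asarray(masked_intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("first_order_stats requires at least one intensity")
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev ** 2)
    m3 = np.mean(dev ** 3)
    m4 = np.mean(dev ** 4)
    probs = _histogram_probs(x, n_bins)
    energy = float(np.sum(x ** 2))
    return {
        "energy": energy,
        "total_energy": float(voxel_volume) * energy,
        "entropy": float(-np.sum(probs * np.log2(probs))),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "mean": float(mean),
        "median": float(np.median(x)),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(dev))),
        "root_mean_square": float(np.sqrt(np.mean(x ** 2))),
        "skewness": float(m3 / m2 ** 1.5) if m2 > 0 else 0.0,
        "kurtosis": float(m4 / m2 ** 2) if m2 > 0 else 0.0,
        "standard_deviation": float(np.sqrt(m2)),
        "uniformity": float(np.sum(probs ** 2)),
        "variance": float(m2),
    }
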