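"""First-order (intensity histogram) statistics of a masked region."""

from __future__ import annotations

import numpy as np

__all__ = ["compute_first_order"]


def compute_first_order(
    values: np.ndarray,
    n_bins: int = 32,
    pixel_volume: float = 1.0,
    prefix: str = "fo_",
) -> dict[str, float]:
    """The 19-feature first-order set.

    ``values`` are the raw (not discretized) intensities of the masked
    region; entropy and uniformity are computed on an equal-width
    ``n_bins`` histogram of those values (entropy in bits).  Skewness and
    kurtosis are the population moments (kurtosis not excess-corrected, so
    a normal sample gives ≈3); both are defined as 0 for a constant region.
    ``pixel_volume`` (mm² for 2D regions) scales total energy.
    """
    x = np.asarray(values, float).ravel()
    if x.size == 0:
        raise ValueError("empty value set")
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(inner - inner.mean()))) if inner.size else 0.0

    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins)
    else:
        hist = np.array([x.size])
    p = hist / hist.sum()
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    uniformity = float(np.sum(p**2))

    if sd > 0:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew = kurt = 0.0

    energy = float(np.sum(x**2))
    return {
        prefix + "Energy": energy,
        prefix + "TotalEnergy": float(pixel_volume) * energy,
        prefix + "Entropy": entropy,
        prefix + "Minimum": float(x.min()),
        prefix + "Percentile10": float(p10),
        prefix + "Percentile90": float(p90),
        prefix + "Maximum": float(x.max()),
        prefix + "Mean": mean,
        prefix + "Median": float(p50),
        prefix + "InterquartileRange": float(p75 - p25),
        prefix + "Range": float(x.max() - x.min()),
        prefix + "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        prefix + "RobustMeanAbsoluteDeviation": rmad,
        prefix + "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        prefix + "StandardDeviation": sd,
        prefix + "Skewness": skew,
        prefix + "Kurtosis": kurt,
        prefix + "Variance": var,
        prefix + "Uniformity": uniformity,
    }
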