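"""The 18 standard first-order (intensity histogram) features."""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    image: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float = 1.0,
    n_bins: int = 32,
) -> dict[str, float]:
    """First-order statistics of the ROI intensity distribution.

    Entropy and uniformity use an equal-width histogram with ``n_bins``
    bins over the ROI range; skewness and kurtosis are population moments
    (kurtosis is not excess-corrected, so a Gaussian gives ~3).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(image, dtype=float)[mask]
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = float((dev**2).mean())
    sd = np.sqrt(m2)

    if x.max() > x.min():
        counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    else:
        counts = np.array([n])
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if m2 > 0:
        skew = float((dev**3).mean() / m2**1.5)
        kurt = float((dev**4).mean() / m2**2)
    else:
        skew, kurt = 0.0, 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(dev).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": uniformity,
    }
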