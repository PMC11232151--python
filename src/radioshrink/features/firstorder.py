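"""First-order intensity statistics (18 features).

Entropy and Uniformity are computed on the discretized gray levels; all
other statistics act on the raw intensities inside the mask.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def compute_first_order_features(values: np.ndarray, levels: np.ndarray,
                                 voxel_volume_mm3: float = 1.0) -> dict[str, float]:
    """The standard 18 first-order statistics.

    Parameters
    ----------
    values:
        Raw intensities inside the mask (1D).
    levels:
        Discretized gray levels for the same voxels (1D, >= 1), used for
        Entropy and Uniformity.
    voxel_volume_mm3:
        Physical voxel volume; only TotalEnergy depends on it.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("first-order features require a nonempty region")
    lv = np.asarray(levels).ravel()
    if lv.size != v.size:
        raise ValueError("levels and values must be the same length")

    n = v.size
    mean = float(v.mean())
    p10, q1, med, q3, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    counts = np.bincount(lv)[1:]
    p = counts[counts > 0] / n
    robust = v[(v >= p10) & (v <= p90)]

    if n > 1 and v.std() > 0:
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0

    return {
        "Energy": float((v ** 2).sum()),
        "TotalEnergy": float(voxel_volume_mm3 * (v ** 2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(med),
        "InterquartileRange": float(q3 - q1),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((v ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(v.var()),
        "Uniformity": float((p ** 2).sum()),
    }
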