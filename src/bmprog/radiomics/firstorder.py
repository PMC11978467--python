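"""First-order intensity statistics within the lesion ROI.

Entropy and Uniformity operate on the fixed-bin-count histogram shared with
the texture matrices; the remaining statistics use raw (normalized) values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

EPS = np.spacing(1.0)

FIRSTORDER_FEATURES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
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


def firstorder_features(
    values: np.ndarray, discretized: np.ndarray, voxel_volume_mm3: float
) -> dict[str, float]:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no voxels in ROI")
    n = x.size
    p = np.bincount(discretized.ravel())[1:].astype(float)
    p = p[p > 0] / n

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    mean = float(x.mean())
    if x.std() == 0:
        skew, kurt = 0.0, 0.0
    else:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x, fisher=False))  # not excess kurtosis

    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume_mm3 * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p + EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(x.var()),
        "Uniformity": float(np.sum(p**2)),
    }
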