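"""Inter-feature redundancy filtering on training rows only."""

from __future__ import annotations

import numpy as np


def correlation_filter(train_features: np.ndarray, cutoff: float = 0.8) -> np.ndarray:
    """Greedy keep-first filter: retain a feature iff |Pearson r| <= cutoff
    against every feature already retained. Zero-variance features (r is
    undefined) are dropped up front. Returns retained column indices in the
    original feature order.
    """
    x = np.asarray(train_features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 training rows")
    # a column is constant iff its range is zero (var can pick up float dust)
    candidates = np.flatnonzero(np.ptp(x, axis=0) > 0)
    if len(candidates) == 0:
        return candidates
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x[:, candidates], rowvar=False)
    corr = np.atleast_2d(corr)
    kept: list[int] = []
    for pos in range(len(candidates)):
        if all(abs(corr[pos, kpos]) <= cutoff for kpos in kept):
            kept.append(pos)
    return candidates[kept]
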