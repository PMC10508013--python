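"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np


def weighted_quantile(values, weights, q: float) -> float:
    """Lower weighted quantile: smallest x whose cumulative weight reaches q.

    Ties and repeated values share the lower group by construction. Weights
    must be positive; q in [0, 1].
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_quantile of an empty sequence")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile must lie in [0, 1], got {q}")
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    cw = np.cumsum(weights[order])
    target = q * cw[-1]
    # first index with cumulative weight >= target (lower convention)
    idx = int(np.searchsorted(cw, target, side="left"))
    idx = min(idx, v.size - 1)
    return float(v[idx])


def weighted_median(values, weights) -> float:
    """Lower weighted median (cumulative weight >= 50%)."""
    return weighted_quantile(values, weights, 0.5)
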