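"""Shared statistical primitives used across modules."""

from __future__ import annotations

import numpy as np


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, returned in the
    original input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0 / SD 1; degenerate (zero-variance) input -> all 0."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd
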