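"""Small shared statistical primitives."""

from __future__ import annotations

import numpy as np


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard step-up procedure with monotonicity enforcement: sort the m
    p-values, multiply the i-th smallest by m/i, take the running minimum
    from the largest rank down, and cap at 1.  Order-preserving under
    ranking; an empty input yields an empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-d vector of p-values")
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
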