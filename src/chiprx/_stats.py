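"""Shared statistical primitives."""

from __future__ import annotations

import numpy as np


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR).

    NaN entries are excluded from the universe and returned as NaN.
    Values outside [0,1] are an error.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = ~np.isnan(p)
    pf = p[finite]
    if ((pf < 0) | (pf > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="stable")
    ranked = pf[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adjusted, 1.0)
    out[finite] = result
    return out
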