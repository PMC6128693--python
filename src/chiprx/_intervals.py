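"""Vectorized half-open interval primitives.

Everything in this package is 0-based, half-open. These helpers operate on
parallel numpy arrays of starts/ends; callers handle chromosome grouping.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(
    starts: np.ndarray, ends: np.ndarray, gap: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Merge intervals, joining any pair separated by at most ``gap`` bp.

    With gap=0 touching intervals ([0,10), [10,20)) are merged; output is
    sorted and pairwise disjoint.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    cummax_e = np.maximum.accumulate(e)
    new_run = np.empty(s.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > cummax_e[:-1] + gap
    run_idx = np.flatnonzero(new_run)
    return s[run_idx], np.maximum.reduceat(e, run_idx)


def overlap_with_merged(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    m_starts: np.ndarray,
    m_ends: np.ndarray,
) -> np.ndarray:
    """Total overlap (bp) of each query interval with a merged interval set.

    ``m_starts``/``m_ends`` must be sorted and pairwise disjoint (as produced
    by :func:`merge_intervals`).
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if m_starts.size == 0 or q_starts.size == 0:
        return np.zeros(q_starts.size, dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(m_ends - m_starts)))
    lo = np.searchsorted(m_ends, q_starts, side="right")
    hi = np.searchsorted(m_starts, q_ends, side="left")
    valid = hi > lo
    total = cum[np.maximum(hi, lo)] - cum[lo]
    lo_c = np.minimum(lo, m_starts.size - 1)
    first_trim = np.maximum(0, q_starts - m_starts[lo_c])
    last_trim = np.maximum(0, m_ends[np.maximum(hi, 1) - 1] - q_ends)
    return np.where(valid, total - first_trim - last_trim, 0)


def clip_intervals(
    starts: np.ndarray, ends: np.ndarray, lo: int, hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """Clip intervals to window [lo, hi), dropping those that fall outside."""
    s = np.maximum(np.asarray(starts, dtype=np.int64), lo)
    e = np.minimum(np.asarray(ends, dtype=np.int64), hi)
    keep = s < e
    return s[keep], e[keep]


def count_overlapping(
    read_starts_sorted: np.ndarray,
    read_ends_sorted: np.ndarray,
    w_starts: np.ndarray,
    w_ends: np.ndarray,
) -> np.ndarray:
    """Number of reads overlapping each window by >=1 bp.

    ``read_starts_sorted`` and ``read_ends_sorted`` are each sorted
    ascending (independently — they need not stay paired). A read overlaps
    [ws, we) iff start < we and end > ws, so the count is
    #(start < we) - #(end <= ws).
    """
    n_start_before = np.searchsorted(read_starts_sorted, w_ends, side="left")
    n_end_before = np.searchsorted(read_ends_sorted, w_starts, side="right")
    return n_start_before - n_end_before
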