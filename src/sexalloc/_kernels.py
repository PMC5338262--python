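"""Numba kernels for the hot inner loops of parent sampling.

Both kernels replace full-range binary searches (cache-miss bound at large N)
with access patterns that stay inside small contiguous regions: a linear merge
against sorted lottery targets, and per-group bounded binary searches.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def merge_sample_sorted(cumw: np.ndarray, targets: np.ndarray, out: np.ndarray) -> None:
    """For each ascending target, the first index with ``cumw[idx] > target``.

    ``targets`` must be sorted ascending and lie in ``[0, cumw[-1])``; the
    result is the weighted-lottery draw for order-statistic targets, computed
    by a single linear merge.
    """
    m = cumw.shape[0]
    j = 0
    for i in range(targets.shape[0]):
        t = targets[i]
        while j < m - 1 and cumw[j] <= t:
            j += 1
        out[i] = j


@njit(cache=False)
def segment_weighted_draw(
    cumw: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    u: np.ndarray,
    out: np.ndarray,
) -> None:
    """Weighted draw restricted to contiguous segments of a cumulative-sum
    vector.

    For row ``i`` the draw is over positions ``lo[i] .. hi[i]-1`` of the
    underlying weight vector, with probability proportional to each weight;
    ``u[i]`` is a uniform variate in [0, 1).  Segments must be non-empty with
    positive total weight.
    """
    for i in range(u.shape[0]):
        a = lo[i]
        b = hi[i] - 1
        base = cumw[a - 1] if a > 0 else 0.0
        t = base + u[i] * (cumw[b] - base)
        while a < b:
            mid = (a + b) // 2
            if cumw[mid] <= t:
                a = mid + 1
            else:
                b = mid
        out[i] = a
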