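"""Hartigan's dip statistic of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
distribution function and any unimodal distribution function (convex below
the mode, concave above it, an atom permitted at the mode).  Unimodal samples
have dips near the attainable minimum 1/(2n); a balanced pair of
well-separated clusters approaches the maximum of 1/4.

Computed by the classical modal-interval shrinkage: on the current candidate
modal interval, build the greatest convex minorant (through the lower step
corners of the ecdf) and the least concave majorant (upper corners).  The
maximum vertical gap between the two hull curves is attained at a hull
vertex; the modal interval shrinks to the pair of opposing vertices realizing
it, while the ecdf's deviations from the hulls outside the new interval are
accumulated (an optimal unimodal cdf can split each deviation symmetrically,
hence the final division by two).  Iteration stops when the bridge gap no
longer exceeds the accumulated deviation.  Working in index space with
duplicates retained makes a point mass free when it sits at the mode: the
interval shrinks into the vertical step and the remaining gap vanishes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dip_statistic"]


@njit(cache=False)
def _lower_hull(x, low, high, out):
    """Indices of the lower convex hull of (x_i, i), i in [low, high]."""
    m = 0
    for i in range(low, high + 1):
        while m >= 2:
            a, b = out[m - 2], out[m - 1]
            # drop b if it is on/above segment a--i
            if (b - a) * (x[i] - x[a]) >= (i - a) * (x[b] - x[a]):
                m -= 1
            else:
                break
        out[m] = i
        m += 1
    return m


@njit(cache=False)
def _upper_hull(x, low, high, out):
    """Indices of the upper concave hull of (x_i, i + 1), i in [low, high]."""
    m = 0
    for i in range(low, high + 1):
        while m >= 2:
            a, b = out[m - 2], out[m - 1]
            if (b - a) * (x[i] - x[a]) <= (i - a) * (x[b] - x[a]):
                m -= 1
            else:
                break
        out[m] = i
        m += 1
    return m


@njit(cache=False)
def _interp(x, idx_a, idx_b, val_a, val_b, xq):
    if x[idx_b] == x[idx_a]:
        return val_a
    return val_a + (val_b - val_a) * (xq - x[idx_a]) / (x[idx_b] - x[idx_a])


@njit(cache=False)
def _dip_core(x):
    n = x.size
    if n < 2 or x[0] == x[n - 1]:
        return 0.0
    low, high = 0, n - 1
    d_accum = 0.0
    gcm = np.empty(n, dtype=np.int64)
    lcm = np.empty(n, dtype=np.int64)
    for _it in range(2 * n + 10):
        if x[low] == x[high]:
            return d_accum / (2.0 * n)
        ng = _lower_hull(x, low, high, gcm)
        nl = _upper_hull(x, low, high, lcm)
        # largest gap between the hull curves, attained at a hull vertex
        d = -1.0
        ig, ih = low, high
        seg = 0
        for t in range(ng):
            i = gcm[t]
            while seg < nl - 1 and x[lcm[seg + 1]] < x[i]:
                seg += 1
            s2 = min(seg + 1, nl - 1)
            lcm_val = _interp(
                x, lcm[seg], lcm[s2], float(lcm[seg] + 1), float(lcm[s2] + 1), x[i]
            )
            gap = lcm_val - float(i)
            if gap > d:
                d = gap
                ig = i
                ih = lcm[s2]
        seg = 0
        for t in range(nl):
            i = lcm[t]
            while seg < ng - 1 and x[gcm[seg + 1]] < x[i]:
                seg += 1
            s2 = min(seg + 1, ng - 1)
            # left endpoint of the gcm segment strictly covering x_i
            gcm_val = _interp(
                x, gcm[seg], gcm[s2], float(gcm[seg]), float(gcm[s2]), x[i]
            )
            gap = float(i + 1) - gcm_val
            if gap > d:
                d = gap
                ig = gcm[seg]
                ih = i
        if ih < ig:
            ig, ih = ih, ig
        if d <= d_accum:
            return d_accum / (2.0 * n)
        # deviations of the ecdf from the hulls outside the new modal interval
        seg = 0
        for i in range(low, ig + 1):
            while seg < ng - 1 and gcm[seg + 1] < i:
                seg += 1
            s2 = min(seg + 1, ng - 1)
            fit = _interp(x, gcm[seg], gcm[s2], float(gcm[seg]), float(gcm[s2]), x[i])
            dev = float(i + 1) - fit
            if dev > d_accum:
                d_accum = dev
        seg = 0
        for i in range(ih, high + 1):
            while seg < nl - 1 and lcm[seg + 1] < i:
                seg += 1
            s2 = min(seg + 1, nl - 1)
            fit = _interp(x, lcm[seg], lcm[s2], float(lcm[seg] + 1), float(lcm[s2] + 1), x[i])
            dev = fit - float(i)
            if dev > d_accum:
                d_accum = dev
        if ig == low and ih == high:
            return max(d_accum, d) / (2.0 * n)
        low, high = ig, ih
    return max(d_accum, d) / (2.0 * n)  # pragma: no cover - iteration guard


def dip_statistic(sample) -> float:
    """Dip statistic of a 1-D sample; 0 for fewer than two distinct values."""
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty sample")
    return float(_dip_core(x))
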