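"""Exact small-sample dip oracle, straight from the definition.

For every candidate mode placement (a continuous mode at grid positions
inside each inter-point interval, or an atom at a sample point) a linear
program finds the unimodal cdf minimizing the sup-norm band width against the
empirical cdf: band constraints at each point, monotonicity, nondecreasing
slopes below the mode and nonincreasing above it.  The dip is the minimum
over placements.  Independent of the hull-based production algorithm.
"""
import numpy as np
from scipy.optimize import linprog


def _solve(points, lo, hi, convex_triples, concave_triples):
    m = len(points)
    A_ub, b_ub = [], []
    for i in range(m):
        row = [0.0] * (m + 1)
        row[i] = 1.0
        row[m] = -1.0
        A_ub.append(row)
        b_ub.append(hi[i])
        row = [0.0] * (m + 1)
        row[i] = -1.0
        row[m] = -1.0
        A_ub.append(row)
        b_ub.append(-lo[i])
    for i in range(m - 1):  # monotone
        row = [0.0] * (m + 1)
        row[i] = 1.0
        row[i + 1] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)
    for (i, j, k) in convex_triples:  # slope(i,j) <= slope(j,k)
        dx1 = points[j] - points[i]
        dx2 = points[k] - points[j]
        row = [0.0] * (m + 1)
        row[i] += -1.0 / dx1
        row[j] += 1.0 / dx1 + 1.0 / dx2
        row[k] += -1.0 / dx2
        A_ub.append(row)
        b_ub.append(0.0)
    for (i, j, k) in concave_triples:  # slope(i,j) >= slope(j,k)
        dx1 = points[j] - points[i]
        dx2 = points[k] - points[j]
        row = [0.0] * (m + 1)
        row[i] += 1.0 / dx1
        row[j] += -1.0 / dx1 - 1.0 / dx2
        row[k] += 1.0 / dx2
        A_ub.append(row)
        b_ub.append(0.0)
    c = [0.0] * m + [1.0]
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=[(0.0, 1.0)] * m + [(0.0, 0.5)], method="highs")
    return res.fun if res.success else np.inf


def dip_lp_oracle(sample, p_grid=15):
    x = np.sort(np.asarray(sample, float))
    u, counts = np.unique(x, return_counts=True)
    K, n = u.size, x.size
    if K < 2:
        return 0.0
    cum = np.cumsum(counts)
    F_hi = cum / n
    F_lo = (cum - counts) / n
    band_lo = list(F_hi)   # value-side: v >= F_hi - t
    band_hi = list(F_lo)   # left-limit side: v <= F_lo + t
    best = np.inf
    # mode strictly inside interval (u[m-1], u[m]) with continuous value y
    for mi in range(1, K):
        for frac in np.linspace(0.02, 0.98, p_grid):
            p = u[mi - 1] + frac * (u[mi] - u[mi - 1])
            pts = list(u[:mi]) + [p] + list(u[mi:])
            lo = band_lo[:mi] + [F_lo[mi]] + band_lo[mi:]
            hi = band_hi[:mi] + [F_lo[mi]] + band_hi[mi:]
            conv = [(i, i + 1, i + 2) for i in range(mi - 1)]  # through mode idx mi
            conc = [(i, i + 1, i + 2) for i in range(mi, len(pts) - 2)]
            best = min(best, _solve(pts, lo, hi, conv, conc))
    # atom at sample point j: left limit ell (convex end), value v (concave start)
    for j in range(K):
        eps = 1e-7 * (u[-1] - u[0])
        pts = list(u[: j + 1]) + [u[j] + eps] + list(u[j + 1 :])
        lo = band_lo[:j] + [F_lo[j]] + [F_hi[j]] + band_lo[j + 1 :]
        hi = band_hi[:j] + [F_lo[j]] + [F_hi[j]] + band_hi[j + 1 :]
        conv = [(i, i + 1, i + 2) for i in range(j - 1)]       # chain 0..j (ell at j)
        conc = [(i, i + 1, i + 2) for i in range(j + 1, len(pts) - 2)]  # from v
        best = min(best, _solve(pts, lo, hi, conv, conc))
    return best


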