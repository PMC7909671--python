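"""Measurement layer: approach direction, G-matrix orientation, branching
onset/completion, branching direction, branch counts, 3-D branching angles and
final-outcome classification.

All angle conventions: the direction of approach is the angle of the vector
from the branching point to the initial phenotype, in (-pi, pi] (a population
starting bottom-left of the branching point approaches from -3pi/4).  Line-like
quantities (G-matrix orientation, branching direction) are axial and reported
mod pi in [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from scipy.spatial import cKDTree

from .dip import dip_statistic

__all__ = [
    "approach_direction",
    "g_matrix",
    "g_orientation",
    "leading_eigenvector",
    "detect_onset",
    "detect_completion_ibs",
    "branching_direction",
    "count_branches",
    "cluster_means",
    "Angles3D",
    "angles_3d",
    "classify_outcome",
    "OutcomeLabel",
    "DIP_COMPLETION_THRESHOLD",
]

#: bimodality level of the 1-D projection at which branching counts as complete
DIP_COMPLETION_THRESHOLD = 0.15


def approach_direction(z0, z_star) -> float:
    """Angle of the line from the branching point z* to the initial phenotype."""
    v = np.asarray(z0, dtype=float) - np.asarray(z_star, dtype=float)
    if np.allclose(v, 0.0):
        raise ValueError("initial phenotype coincides with z*: direction undefined")
    if v.size != 2:
        raise ValueError("approach_direction is 2-D; use angles_3d for k=3")
    return float(np.arctan2(v[1], v[0]))


def g_matrix(sample, weights=None) -> np.ndarray:
    """(Weighted) trait variance-covariance matrix of a phenotype sample."""
    x = np.atleast_2d(np.asarray(sample, dtype=float))
    if weights is None:
        return np.cov(x, rowvar=False, bias=True)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = w @ x
    d = x - mu
    return (d * w[:, None]).T @ d


def leading_eigenvector(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    vals, vecs = np.linalg.eigh(cov)
    if vals[-1] <= 0.0:
        raise ValueError("zero covariance: orientation undefined")
    return vecs[:, -1]


def g_orientation(sample_or_cov, weights=None) -> float:
    """Orientation (mod pi) of the leading eigenvector of the G-matrix.

    Accepts either a sample of phenotypes (rows) or a ready covariance matrix.
    A long axis along z2 gives pi/2; strong positive covariance gives pi/4 and
    strong negative covariance 3pi/4.
    """
    arr = np.asarray(sample_or_cov, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and np.allclose(arr, arr.T, atol=1e-10):
        cov = arr
    else:
        cov = g_matrix(arr, weights)
    if cov.shape != (2, 2):
        raise ValueError("g_orientation is 2-D; use leading_eigenvector for k>2")
    v = leading_eigenvector(cov)
    return float(np.arctan2(v[1], v[0]) % np.pi)


def _fitness_variance_series(trajectory):
    fv = getattr(trajectory, "fitness_variance", trajectory)
    return np.asarray(fv, dtype=float)


def detect_onset(trajectory, completion_generation: int | None = None) -> int:
    """Generation at which the fitness variance is lowest (onset of branching).

    The first generation is excluded (no mutational variation yet); ties go to
    the earliest generation.  The search starts at the series' global maximum:
    fitness variance is largest during the steep part of the approach and
    dips as the population closes in on the singular point, so searching after
    the peak guards against spurious minima in the initial relaxation of the
    founding population.  The search runs up to the completion generation when
    one is known.  Series index 0 is generation 1.
    """
    fv = _fitness_variance_series(trajectory)
    if completion_generation is None:
        completion_generation = getattr(trajectory, "completion_generation", None)
    stop = len(fv) if completion_generation is None else min(len(fv), completion_generation)
    if stop < 2:
        raise ValueError("need at least generations 1..3 to locate the onset")
    peak = int(np.argmax(fv[1:stop])) + 1
    return int(np.argmin(fv[peak:stop])) + peak + 1  # 1-based generations


def projected_dip(traits: np.ndarray, jitter: float = 0.0, rng=None) -> float:
    """Dip statistic of the sample projected on its leading covariance axis.

    ``jitter`` adds Normal(0, jitter) measurement noise to the projection
    before the dip.  The dip is scale-free, so the clonal atoms of a
    finite-population sample would otherwise register as spurious modes; a
    jitter at the mutation-step scale smears structure below that scale while
    leaving genuinely branched (widely separated) clusters untouched.
    """
    traits = np.asarray(traits, dtype=float)
    cov = g_matrix(traits)
    try:
        axis = leading_eigenvector(cov)
    except ValueError:
        return 0.0
    proj = traits @ axis
    if jitter > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        proj = proj + rng.normal(0.0, jitter, size=proj.shape)
    return dip_statistic(proj)


def detect_completion_ibs(trajectory) -> int | None:
    """First snapshot generation whose projected dip exceeds the threshold."""
    snaps = getattr(trajectory, "snapshots", trajectory)
    for gen, traits in snaps:
        if projected_dip(traits) > DIP_COMPLETION_THRESHOLD:
            return int(gen)
    return None


def branching_direction(snapshot, weights=None) -> float:
    """Direction of branching: G-matrix orientation of the completion snapshot."""
    return g_orientation(snapshot, weights)


def count_branches(
    snapshot, eps: float | None = None, min_pts: int | None = None
) -> int:
    """Number of phenotype clusters (density-based; noise points not counted).

    Defaults: ``eps`` is three times the median nearest-neighbour distance and
    ``min_pts = max(5, n/200)``, which keeps the rule scale-free across
    mutation-size presets.
    """
    x = np.atleast_2d(np.asarray(snapshot, dtype=float))
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty snapshot")
    if min_pts is None:
        min_pts = max(5, n // 200)
    if n <= min_pts:
        return 1
    if eps is None:
        eps = _default_eps(x)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(x).labels_
    return int(len(set(labels) - {-1}))


def _default_eps(x: np.ndarray) -> float:
    """Neighbourhood radius for branch counting.

    Three times the median positive nearest-neighbour distance (zero
    distances between clonal copies are ignored), floored at half the RMS
    per-axis spread: in dense finite-population samples the raw
    nearest-neighbour scale is far below the width of a single branch and
    would shatter it, while well-separated branches sit many spreads apart.
    """
    nn = cKDTree(x).query(x, k=2)[0][:, 1]
    pos = nn[nn > 0.0]
    nn_scale = 3.0 * float(np.median(pos)) if pos.size else 0.0
    spread = float(np.sqrt(np.mean(np.var(x, axis=0))))
    return max(nn_scale, 0.5 * spread, 1e-12)


def cluster_means(snapshot, eps=None, min_pts=None) -> np.ndarray:
    """Mean phenotype of each density-based cluster (noise excluded)."""
    x = np.atleast_2d(np.asarray(snapshot, dtype=float))
    n = x.shape[0]
    if min_pts is None:
        min_pts = max(5, n // 200)
    if eps is None:
        eps = _default_eps(x)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(x).labels_
    ids = sorted(set(labels) - {-1})
    if not ids:
        return x.mean(axis=0, keepdims=True)
    return np.vstack([x[labels == i].mean(axis=0) for i in ids])


@dataclass(frozen=True)
class Angles3D:
    """Branching angles for k = 3: phi within the approach plane Q, psi within
    the perpendicular plane P, both measured from the intersection line I."""

    phi: float
    psi: float


def angles_3d(
    branch_line,
    z0,
    z_star,
    reference_point=(1.0, 2.0, 3.0),
) -> Angles3D:
    """Characterize a 3-D branching direction relative to the approach.

    Plane Q contains the approach line (z0 to z*) and an arbitrary fixed
    reference point; plane P is perpendicular to the approach through z*;
    I = P intersect Q.  ``phi`` is the angle between I and the projection of
    the branch line L on Q; ``psi`` between I and the projection on P.  L is
    folded to have a nonnegative component along the approach direction
    (ties broken toward positive I), so phi lies in [0, pi] with perpendicular
    branching at 0 or pi.
    """
    z0 = np.asarray(z0, dtype=float)
    z_star = np.asarray(z_star, dtype=float)
    d = np.asarray(branch_line, dtype=float)
    if z0.shape != (3,) or d.shape != (3,):
        raise ValueError("angles_3d requires k = 3")
    nd = np.linalg.norm(d)
    if nd == 0.0:
        raise ValueError("degenerate branch line")
    d = d / nd
    v = z0 - z_star
    nv = np.linalg.norm(v)
    if nv == 0.0:
        raise ValueError("z0 coincides with z*")
    e_app = v / nv
    r = np.asarray(reference_point, dtype=float) - z_star
    r_perp = r - (r @ e_app) * e_app
    nr = np.linalg.norm(r_perp)
    if nr < 1e-12:
        raise ValueError("reference point lies on the approach line; pick another")
    e_i = r_perp / nr  # direction of I (in both P and Q)
    e_w = np.cross(e_app, e_i)  # completes P's basis, perpendicular to Q

    # L is axial (the two strains have no canonical order): fold so the
    # I-component is nonnegative; ties broken toward the approach direction.
    # Perpendicular branching then scatters phi symmetrically about 0 (mod 2pi)
    # and the antipode pi appears by axial mirroring.
    if d @ e_i < -1e-12 or (abs(d @ e_i) <= 1e-12 and d @ e_app < 0.0):
        d = -d
    dq = np.array([d @ e_i, d @ e_app])  # L projected on Q, basis (I, approach)
    dp = np.array([d @ e_i, d @ e_w])  # L projected on P, basis (I, w)

    def _wrap(angle: float) -> float:
        a = angle % (2.0 * np.pi)
        return 0.0 if 2.0 * np.pi - a < 1e-9 else a

    # a projection into the null space leaves that angle undefined (NaN flag)
    phi = np.nan if np.linalg.norm(dq) < 1e-12 else _wrap(float(np.arctan2(dq[1], dq[0])))
    psi = np.nan if np.linalg.norm(dp) < 1e-12 else _wrap(float(np.arctan2(dp[1], dp[0])))
    return Angles3D(phi=phi, psi=psi)


@dataclass(frozen=True)
class OutcomeLabel:
    """Final dimorphic outcome relative to the branching point's quadrants."""

    label: str  # DOL / CD / OTHER
    occupancy: frozenset = field(default_factory=frozenset)
    warning: str | None = None


def classify_outcome(strains, z_star, tol_band: float = 0.0) -> OutcomeLabel:
    """Classify a final strain configuration as division of labor or
    cooperator-defector.

    Quadrants are delimited by the axis-parallel lines through z*.  DOL means
    the strains occupy exactly the (+,-) and (-,+) quadrants (complementary
    specialists); CD means (+,+) and (-,-) (a generalist cooperator plus a
    defector).  A strain within ``tol_band`` of a dividing line cannot be
    assigned and forces OTHER with a warning.
    """
    x = np.atleast_2d(np.asarray(strains, dtype=float))
    z_star = np.asarray(z_star, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two strains to classify an outcome")
    rel = x - z_star
    if np.any(np.abs(rel) <= tol_band):
        return OutcomeLabel(
            label="OTHER",
            occupancy=frozenset(),
            warning="strain within tolerance band of a dividing line",
        )
    occupancy = frozenset(tuple("+" if v > 0 else "-" for v in row) for row in rel)
    if occupancy == {("+", "-"), ("-", "+")}:
        label = "DOL"
    elif occupancy == {("+", "+"), ("-", "-")}:
        label = "CD"
    else:
        label = "OTHER"
    return OutcomeLabel(label=label, occupancy=occupancy)
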