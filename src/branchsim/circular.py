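"""Circular summaries for directional and axial (mod-pi) angle data.

Branching directions and G-matrix orientations are axial: an angle and its
antipode describe the same line, so statistics are computed on doubled angles
and mapped back.  Approach directions live on the full circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircularSummary",
    "circular_summary",
    "rayleigh_test",
    "circular_correlation",
    "circular_distance",
    "axial_mode_near_zero",
]


@dataclass(frozen=True)
class CircularSummary:
    mean: float  # circular mean on the native scale, in [0, period)
    concentration: float  # mean resultant length in [0, 1]
    p_uniform: float  # Rayleigh uniformity p-value
    n: int


def _to_circle(angles, period: float) -> np.ndarray:
    angles = np.asarray(angles, dtype=float).ravel()
    if angles.size == 0:
        raise ValueError("no angles given")
    return angles * (2.0 * np.pi / period)


def rayleigh_test(angles, period: float = 2.0 * np.pi) -> float:
    """Rayleigh test p-value against uniformity on the circle.

    Uses the standard series correction in 1/n; accurate for n >= 10.
    """
    theta = _to_circle(angles, period)
    n = theta.size
    rbar = np.hypot(np.cos(theta).mean(), np.sin(theta).mean())
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(min(max(p, 0.0), 1.0))


def circular_summary(angles, period: float = np.pi) -> CircularSummary:
    """Circular mean, concentration and uniformity p-value.

    With ``period = pi`` (axial data) the angles are doubled before averaging,
    so antipodal wrap-around is respected: {0.01, pi - 0.01} averages to ~0.
    The mean is undefined (raises) when the resultant length vanishes.
    """
    theta = _to_circle(angles, period)
    n = theta.size
    c, s = np.cos(theta).mean(), np.sin(theta).mean()
    rbar = float(np.hypot(c, s))
    if rbar < 1e-12:
        raise ValueError("resultant length ~ 0: circular mean undefined")
    mean = (np.arctan2(s, c) * period / (2.0 * np.pi)) % period
    return CircularSummary(
        mean=float(mean), concentration=rbar, p_uniform=rayleigh_test(angles, period), n=n
    )


def circular_distance(a: float, b: float, period: float = np.pi) -> float:
    """Shortest distance between two angles on a circle of the given period."""
    d = (a - b) % period
    return float(min(d, period - d))


def circular_correlation(a, b, period: float = np.pi) -> float:
    """Circular-circular association coefficient (sine-moment form).

    Angles are mapped to the full circle first (doubling for axial data), then
    the Jammalamadaka-SenGupta correlation is computed.
    """
    ta = _to_circle(a, period)
    tb = _to_circle(b, period)
    if ta.size != tb.size or ta.size < 2:
        raise ValueError("need two equal-length angle arrays")
    ma = np.arctan2(np.sin(ta).mean(), np.cos(ta).mean())
    mb = np.arctan2(np.sin(tb).mean(), np.cos(tb).mean())
    sa, sb = np.sin(ta - ma), np.sin(tb - mb)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0.0:
        raise ValueError("degenerate angle set: no dispersion")
    return float((sa * sb).sum() / denom)


def axial_mode_near_zero(angles, kappa: float = 8.0, grid: int = 1024) -> float:
    """Mode of the axially symmetrized circular KDE, as a signed value near 0.

    The sample is mirrored through the origin (each angle also contributes its
    antipode), a von Mises kernel density is evaluated on a grid, and the
    modal pair (m, m + pi) is mapped to its representative in [-pi/2, pi/2).
    Used for axial angle distributions whose modes sit at 0 and pi.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("no angles given")
    data = np.concatenate([a, a + np.pi])
    theta = np.linspace(0.0, 2.0 * np.pi, grid, endpoint=False)
    dens = np.exp(kappa * np.cos(theta[:, None] - data[None, :])).sum(axis=1)
    m = theta[int(np.argmax(dens))]
    return float((m + np.pi / 2.0) % np.pi - np.pi / 2.0)
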