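"""Quantitative-genetics prediction of the within-generation G-matrix change.

For a bivariate-normal trait cloud under a fitness surface with gradient D and
curvature matrix gamma at the mean, one round of selection updates the
variance-covariance matrix as

    G* = G + G (gamma - 2 D D^T) G.

On a straight diagonal approach (D1 = D2 = D, isotropic G = V I, common
curvature Gamma) this reduces to the closed form

    G* = [[V + (Gamma - 2 D^2) V^2,  -2 D^2 V^2],
          [-2 D^2 V^2,               V + (Gamma - 2 D^2) V^2]],

whose off-diagonal is negative: directional selection trims the tails along
the direction of motion, so the cloud elongates perpendicular to it.  The
gradient term here is weighted twice as strongly as in the classical
Lande-Arnold within-generation covariance change; the factor rescales the
magnitude of the loss of variance along the gradient but leaves its sign and
the induced orientation - the quantities the simulation engines probe -
unchanged.
"""

from __future__ import annotations

import numpy as np

from .analysis import g_orientation
from .games import ModelConfig, _check_domain

__all__ = [
    "curvature_matrix",
    "g_after_selection",
    "eq_symmetric_update",
    "predicted_post_selection_orientation",
]


def curvature_matrix(z, model: ModelConfig) -> np.ndarray:
    """Second mutant-derivatives of invasion fitness at the resident ``z``.

    Payoffs are additive across games, so the matrix is diagonal with entries
    ``k w_i (B_i'' - C_i'') = k w_i (-2 a_i b_i + 2 c_i d_i)``; a positive
    diagonal entry at z* marks a fitness minimum (not ESS) in that dimension.
    """
    _check_domain(z, model)
    diag = [s * (g.benefit_curv - g.cost_curv) for g, s in zip(model.games, model.scale)]
    return np.diag(diag)


def g_after_selection(G, gamma, D) -> np.ndarray:
    """One round of selection: ``G* = G + G (gamma - 2 D D^T) G``."""
    G = np.asarray(G, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    D = np.asarray(D, dtype=float).ravel()
    vals = np.linalg.eigvalsh(G)
    if vals[0] < -1e-12:
        raise ValueError("G must be positive semidefinite")
    out = G + G @ (gamma - 2.0 * np.outer(D, D)) @ G
    if not np.allclose(out, out.T, atol=1e-12):
        raise RuntimeError("update lost symmetry")
    return out


def eq_symmetric_update(V: float, Gamma: float, D: float) -> np.ndarray:
    """Closed-form post-selection G for the symmetric diagonal approach."""
    diag = V + (Gamma - 2.0 * D**2) * V**2
    off = -2.0 * D**2 * V**2
    return np.array([[diag, off], [off, diag]])


def predicted_post_selection_orientation(z, G, model: ModelConfig) -> float:
    """Orientation (mod pi) of the trait cloud after one round of selection."""
    from .games import selection_gradient

    D = selection_gradient(z, model)
    gamma = curvature_matrix(z, model)
    return g_orientation(g_after_selection(G, gamma, D))
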