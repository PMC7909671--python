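"""Oligomorphic stochastic simulation: a trait-substitution random walk.

The population is a small set of monomorphic strains at their joint
demographic equilibrium (equal mean payoffs, frequencies from a linear solve).
Each event proposes a mutant from a frequency-weighted parent with Gaussian
trait displacement; the mutant is accepted with probability proportional to
its positive invasion fitness against the current mixture (linear
branching-process approximation).  An accepted mutant replaces its parent
unless parent and mutant are mutually invasible against the updated
background, in which case both are retained - that is how branching appears.
Branching is complete when the set stays polymorphic for a fixed number of
consecutive successful invasions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import g_matrix, g_orientation
from .games import ModelConfig, pairwise_payoff, selection_gradient

__all__ = [
    "Strain",
    "StrainSet",
    "OssConfig",
    "default_s_scale",
    "propose_mutant",
    "attempt_invasion",
    "run_oss",
    "OssResult",
]


@dataclass(frozen=True)
class Strain:
    z: np.ndarray
    freq: float


@dataclass
class StrainSet:
    strains: list
    event_count: int = 0
    polymorphic_streak: int = 0

    @property
    def phenotypes(self) -> np.ndarray:
        return np.array([s.z for s in self.strains])

    @property
    def freqs(self) -> np.ndarray:
        return np.array([s.freq for s in self.strains])


@dataclass(frozen=True)
class OssConfig:
    n: int = 10_000  # nominal population size (enters only via reporting)
    sigma_oss: float = 1.5e-3
    mu: float = 1e-2
    completion_streak: int = 10
    max_events: int = 2_000_000
    strain_cap: int = 6
    s_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_oss <= 0:
            raise ValueError("sigma_oss must be positive")


def default_s_scale(cfg: OssConfig, model: ModelConfig) -> float:
    """Scale turning invasion fitness into an acceptance probability <= 1.

    Uses an upper bound on the selection gradient over the trait box (the
    gradient is linear per dimension, so extremes sit at the box corners)
    times three mutational standard deviations.
    """
    lo = selection_gradient(np.zeros(model.k), model)
    hi = selection_gradient(model.z_max, model)
    dmax = np.maximum(np.abs(lo), np.abs(hi))
    return 3.0 * cfg.sigma_oss * float(np.linalg.norm(dmax))


def canonical_rate(cfg: OssConfig, model: ModelConfig) -> float:
    """Mutation-rate factor of the engine's canonical-equation limit.

    Acceptance probability ``s+/s_scale`` keeps only the uphill half of the
    symmetric proposal distribution, so the expected displacement per proposal
    is ``sigma_oss^2 D(z) / (2 s_scale)``: the trait-substitution sequence
    follows ``dz/dt = m sigma^2 D`` with ``m = 1/(2 s_scale)`` per proposal.
    """
    s_scale = cfg.s_scale if cfg.s_scale is not None else default_s_scale(cfg, model)
    return 1.0 / (2.0 * s_scale)


def _payoff_matrix(phen: np.ndarray, model: ModelConfig) -> np.ndarray:
    m = phen.shape[0]
    pi = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            pi[i, j] = pairwise_payoff(phen[i], phen[j], model)
    return pi


def _equilibrium_freqs(phen: np.ndarray, model: ModelConfig):
    """Equal-mean-payoff frequencies; drops strains that equilibrate at <= 0.

    Returns (kept indices, freqs, common payoff) or None when no interior
    equilibrium exists for any sub-set containing more than zero strains.
    """
    idx = list(range(phen.shape[0]))
    while idx:
        if len(idx) == 1:
            z = phen[idx]
            return idx, np.array([1.0]), pairwise_payoff(z[0], z[0], model)
        pi = _payoff_matrix(phen[idx], model)
        m = len(idx)
        a = np.zeros((m + 1, m + 1))
        a[:m, :m] = pi
        a[:m, m] = -1.0
        a[m, :m] = 1.0
        rhs = np.zeros(m + 1)
        rhs[m] = 1.0
        try:
            sol = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            return None
        q, lam = sol[:m], sol[m]
        if np.all(q > 0.0):
            return idx, q, float(lam)
        # remove the most negative strain and retry
        drop = int(np.argmin(q))
        idx = [v for i, v in enumerate(idx) if i != drop]
    return None


def _mean_payoff_against(z: np.ndarray, phen: np.ndarray, freqs: np.ndarray, model) -> float:
    return float(sum(f * pairwise_payoff(z, p, model) for p, f in zip(phen, freqs)))


def propose_mutant(state: StrainSet, cfg: OssConfig, rng: np.random.Generator, model: ModelConfig):
    """Pick a parent with probability equal to its frequency and perturb it."""
    freqs = state.freqs
    parent = state.strains[int(rng.choice(len(freqs), p=freqs / freqs.sum()))]
    z_mut = parent.z + rng.normal(0.0, cfg.sigma_oss, size=parent.z.shape)
    z_mut = np.clip(z_mut, 0.0, model.z_max)
    return parent, z_mut


def attempt_invasion(
    state: StrainSet,
    z_mut: np.ndarray,
    parent: Strain,
    model: ModelConfig,
    cfg: OssConfig,
    rng: np.random.Generator,
    s_scale: float | None = None,
) -> StrainSet:
    """One invasion attempt; returns the (possibly new) strain set.

    The mutant's growth rate is its mean payoff against the resident mixture
    minus the residents' common equilibrium payoff.  Acceptance probability is
    ``min(1, max(0, s) / s_scale)``.
    """
    if s_scale is None:
        s_scale = cfg.s_scale if cfg.s_scale is not None else default_s_scale(cfg, model)
    phen = state.phenotypes
    freqs = state.freqs
    lam = float(sum(f * _mean_payoff_against(p, phen, freqs, model) for p, f in zip(phen, freqs)))
    s = _mean_payoff_against(z_mut, phen, freqs, model) - lam
    if s <= 0.0 or rng.random() >= min(1.0, s / s_scale):
        return state
    return _apply_invasion(state, z_mut, parent, model, cfg)


def _apply_invasion(
    state: StrainSet, z_mut: np.ndarray, parent: Strain, model: ModelConfig, cfg: OssConfig
) -> StrainSet:
    """Bookkeeping after an accepted mutant: replacement or coexistence."""
    others = [st.z for st in state.strains if st is not parent]
    # background with the parent replaced by the mutant
    bg = np.array(others + [z_mut])
    eq_bg = _equilibrium_freqs(bg, model)
    retain_parent = False
    if eq_bg is not None:
        bidx, bfreq, blam = eq_bg
        w_parent = _mean_payoff_against(parent.z, bg[bidx], bfreq, model) - blam
        retain_parent = w_parent > 0.0
    if retain_parent:
        candidate = np.array([st.z for st in state.strains] + [z_mut])
    else:
        candidate = bg
    eq = _equilibrium_freqs(candidate, model)
    if eq is None:  # singular solve: fall back to plain replacement
        candidate = bg
        eq = _equilibrium_freqs(candidate, model)
        if eq is None:
            return state
    idx, q, _lam = eq
    kept = [(candidate[i], qi) for i, qi in zip(idx, q)]
    if len(kept) > cfg.strain_cap:
        order = np.argsort([f for _z, f in kept])[::-1][: cfg.strain_cap]
        kept = [kept[i] for i in sorted(order)]
        total = sum(f for _z, f in kept)
        kept = [(z, f / total) for z, f in kept]
    new_strains = [Strain(z=np.asarray(z), freq=float(f)) for z, f in kept]
    streak = state.polymorphic_streak + 1 if len(new_strains) >= 2 else 0
    return StrainSet(
        strains=new_strains,
        event_count=state.event_count + 1,
        polymorphic_streak=streak,
    )


@dataclass
class OssResult:
    history: list  # StrainSet after each successful invasion
    completed: bool
    direction: float | None  # branching direction mod pi (k = 2)
    final: StrainSet
    n_proposals: int


def run_oss(
    cfg: OssConfig, model: ModelConfig, z0, rng: np.random.Generator | None = None
) -> OssResult:
    """Iterate propose/attempt until the polymorphic streak reaches the
    completion criterion or the proposal budget is spent."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    z0 = np.clip(np.asarray(z0, dtype=float), 0.0, model.z_max)
    state = StrainSet(strains=[Strain(z=z0, freq=1.0)])
    s_scale = cfg.s_scale if cfg.s_scale is not None else default_s_scale(cfg, model)
    history = []
    proposals = 0
    # proposals are drawn in batches and screened vectorized; the resident
    # state is constant between accepted invasions, so this reproduces the
    # sequential process (draw order per batch: parents, displacements,
    # acceptance coins)
    batch = 256
    k = model.k
    ga = np.array([g.a for g in model.games])
    gb = np.array([g.b for g in model.games])
    gc = np.array([g.c for g in model.games])
    gd = np.array([g.d for g in model.games])
    sc = model.scale
    while proposals < cfg.max_events:
        b = int(min(batch, cfg.max_events - proposals))
        phen = state.phenotypes  # (m, k)
        freqs = state.freqs
        parent_idx = rng.choice(len(freqs), size=b, p=freqs / freqs.sum())
        z_mut = phen[parent_idx] + rng.normal(0.0, cfg.sigma_oss, size=(b, k))
        z_mut = np.clip(z_mut, 0.0, model.z_max)
        coins = rng.random(b)
        # payoff of each mutant against the resident mixture (closed form)
        tot = z_mut[:, None, :] + phen[None, :, :]  # (b, m, k)
        pay = sc * (
            ga * (tot - gb * tot**2) - gc * (z_mut[:, None, :] - gd * z_mut[:, None, :] ** 2)
        )
        w_mut = (pay.sum(axis=2) * freqs[None, :]).sum(axis=1)
        lam = sum(
            f * _mean_payoff_against(p, phen, freqs, model) for p, f in zip(phen, freqs)
        )
        s = w_mut - lam
        hit = np.flatnonzero((s > 0.0) & (coins < np.minimum(1.0, s / s_scale)))
        if hit.size == 0:
            proposals += b
            continue
        h = int(hit[0])
        proposals += h + 1
        parent = state.strains[int(parent_idx[h])]
        new_state = _apply_invasion(state, z_mut[h], parent, model, cfg)
        if new_state is not state:
            state = new_state
            history.append(state)
            if state.polymorphic_streak >= cfg.completion_streak:
                break
    completed = state.polymorphic_streak >= cfg.completion_streak
    direction = None
    if completed and len(state.strains) >= 2 and model.k == 2:
        direction = g_orientation(state.phenotypes, weights=state.freqs)
    return OssResult(
        history=history,
        completed=completed,
        direction=direction,
        final=state,
        n_proposals=proposals,
    )
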