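"""Continuous snowdrift games in k dimensions: payoffs and adaptive dynamics.

Individuals carry a k-vector of investment levels ``z``; each component feeds a
separate pairwise public-goods game with quadratic benefit ``B(x) = a(x - b x^2)``
and cost ``C(x) = c(x - d x^2)``.  A focal player with phenotype ``z'`` meeting a
partner ``z`` earns ``B_i(z_i' + z_i) - C_i(z_i')`` from game ``i``; total payoff
is the (weighted) sum over games.  This module provides the static game algebra:
invasion fitness of rare mutants, the selection gradient, location and
classification of the singular strategy, canonical-equation trajectories and
invasion analysis of dimorphic resident populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DomainError",
    "GameParams",
    "ModelConfig",
    "SingularReport",
    "DimorphicResident",
    "ADConfig",
    "pairwise_payoff",
    "invasion_fitness",
    "selection_gradient",
    "singular_strategy",
    "integrate_canonical_equation",
    "dimorphic_equilibrium",
    "corner_invasion",
    "sample_random_game",
    "DEFAULT_GAME",
]


class DomainError(ValueError):
    """A phenotype lies outside the admissible box [0, z_max]^k."""


@dataclass(frozen=True)
class GameParams:
    """Quadratic cost/benefit parameters of one continuous snowdrift game.

    ``a`` scales the benefit, ``b`` its curvature; ``c`` scales the cost and
    ``d`` its curvature.  Both functions must be increasing on the admissible
    trait range, which bounds investments at ``z_max = min(1/(4b), 1/(2d))``.
    """

    a: float = 1.0
    b: float = 1.05
    c: float = 0.9
    d: float = 1.65

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise ValueError("benefit and cost scales a, c must be positive")
        if self.b <= 0 and self.d <= 0:
            raise ValueError("need b > 0 or d > 0 for a finite trait bound")

    @property
    def z_max(self) -> float:
        bounds = []
        if self.b > 0:
            bounds.append(1.0 / (4.0 * self.b))
        if self.d > 0:
            bounds.append(1.0 / (2.0 * self.d))
        return min(bounds)

    # quadratic benefit/cost and derivatives
    def benefit(self, x):
        return self.a * (x - self.b * x**2)

    def cost(self, x):
        return self.c * (x - self.d * x**2)

    def benefit_prime(self, x):
        return self.a * (1.0 - 2.0 * self.b * x)

    def cost_prime(self, x):
        return self.c * (1.0 - 2.0 * self.d * x)

    @property
    def benefit_curv(self) -> float:
        """B'' (constant for quadratic benefit)."""
        return -2.0 * self.a * self.b

    @property
    def cost_curv(self) -> float:
        """C'' (constant for quadratic cost)."""
        return -2.0 * self.c * self.d


#: the reference parameter set used throughout: branching occurs at z* = 0.0813.
DEFAULT_GAME = GameParams()


@dataclass(frozen=True)
class ModelConfig:
    """k simultaneous games plus fitness weights.

    ``weights`` must sum to one; payoffs enter fitness as ``sum_i k*w_i*P_i`` so
    that uniform weights reproduce the plain sum of per-game payoffs, and for
    k = 2 the asymmetric case is ``weights = (1 - alpha, alpha)`` with the total
    payoff ``2[(1-alpha) P_1 + alpha P_2]``.
    """

    games: tuple[GameParams, ...] = (DEFAULT_GAME, DEFAULT_GAME)
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.games) < 1:
            raise ValueError("need at least one game")
        if self.weights is None:
            object.__setattr__(
                self, "weights", tuple(1.0 / self.k for _ in self.games)
            )
        w = np.asarray(self.weights, dtype=float)
        if len(w) != self.k:
            raise ValueError("one weight per game required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def k(self) -> int:
        return len(self.games)

    @property
    def z_max(self) -> np.ndarray:
        return np.array([g.z_max for g in self.games])

    @property
    def scale(self) -> np.ndarray:
        """Per-game payoff multipliers k*w_i (uniform weights -> plain sum)."""
        return self.k * np.asarray(self.weights, dtype=float)

    @classmethod
    def symmetric(cls, game: GameParams = DEFAULT_GAME, k: int = 2) -> "ModelConfig":
        return cls(games=(game,) * k)

    @classmethod
    def asymmetric(
        cls,
        alpha: float,
        game1: GameParams = DEFAULT_GAME,
        game2: GameParams | None = None,
    ) -> "ModelConfig":
        """Two games with fitness weight ``alpha`` on the second one."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        return cls(games=(game1, game2 or game1), weights=(1.0 - alpha, alpha))


@dataclass(frozen=True)
class SingularReport:
    """Location and per-dimension stability classification of z*."""

    z_star: np.ndarray
    convergent: np.ndarray  # bool per dimension
    ess: np.ndarray  # bool per dimension
    valid: bool  # z* strictly inside (0, z_max) in every dimension

    @property
    def classification(self) -> str:
        if bool(self.convergent.all()) and not bool(self.ess.any()):
            return "branching_point"
        if bool(self.convergent.all()) and bool(self.ess.all()):
            return "ess_attractor"
        if not bool(self.convergent.any()):
            return "repeller"
        return "mixed"


@dataclass(frozen=True)
class DimorphicResident:
    """Two resident strains at their joint demographic equilibrium."""

    strain_a: np.ndarray
    strain_b: np.ndarray
    p: float  # equilibrium frequency of strain_a


@dataclass(frozen=True)
class ADConfig:
    """Canonical-equation scaling: mutation rate factor and mutational variance."""

    m: float = 1.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.m * self.sigma2 <= 0:
            raise ValueError("m * sigma2 must be positive")


def _check_domain(z: np.ndarray, cfg: ModelConfig, tol: float = 1e-9) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape != (cfg.k,):
        raise DomainError(f"phenotype must be a {cfg.k}-vector, got shape {z.shape}")
    if np.any(z < -tol) or np.any(z > cfg.z_max + tol):
        raise DomainError(f"phenotype {z} outside box [0, {cfg.z_max}]")
    return z


def pairwise_payoff(z_focal, z_partner, cfg: ModelConfig) -> float:
    """Payoff to a focal player ``z_focal`` interacting with ``z_partner``."""
    zf = _check_domain(z_focal, cfg)
    zp = _check_domain(z_partner, cfg)
    total = 0.0
    for i, (g, s) in enumerate(zip(cfg.games, cfg.scale)):
        total += s * (g.benefit(zf[i] + zp[i]) - g.cost(zf[i]))
    return float(total)


def invasion_fitness(z_mut, z_res, cfg: ModelConfig) -> float:
    """Growth rate of a rare mutant in a monomorphic resident population.

    ``w(z', z) = P(z', z) - P(z, z)``; identically zero for ``z' = z``.
    """
    return pairwise_payoff(z_mut, z_res, cfg) - pairwise_payoff(z_res, z_res, cfg)


def selection_gradient(z, cfg: ModelConfig) -> np.ndarray:
    """Gradient of invasion fitness in the mutant at the resident ``z``.

    Componentwise ``D_i(z) = k w_i [B_i'(2 z_i) - C_i'(z_i)]``, which for
    quadratic games is linear in ``z_i``.
    """
    z = _check_domain(z, cfg)
    grad = np.empty(cfg.k)
    for i, (g, s) in enumerate(zip(cfg.games, cfg.scale)):
        grad[i] = s * (g.benefit_prime(2.0 * z[i]) - g.cost_prime(z[i]))
    return grad


def singular_strategy(cfg: ModelConfig) -> SingularReport:
    """Locate and classify the joint singular strategy, game by game.

    Each game contributes ``z_i* = (a - c) / (4ab - 2cd)``; convergence
    stability requires ``2B''(2z*) - C''(z*) < 0`` and evolutionary stability
    ``B''(2z*) - C''(z*) < 0``.  All convergent and none ESS means every
    dimension sits at a fitness minimum: an evolutionary branching point.
    """
    k = cfg.k
    z_star = np.empty(k)
    convergent = np.empty(k, dtype=bool)
    ess = np.empty(k, dtype=bool)
    for i, g in enumerate(cfg.games):
        denom = 4.0 * g.a * g.b - 2.0 * g.c * g.d
        if denom == 0.0:
            raise ValueError(f"game {i}: 4ab - 2cd = 0, no isolated singular point")
        z_star[i] = (g.a - g.c) / denom
        convergent[i] = 2.0 * g.benefit_curv - g.cost_curv < 0.0
        ess[i] = g.benefit_curv - g.cost_curv < 0.0
    valid = bool(np.all(z_star > 0.0) and np.all(z_star < cfg.z_max))
    return SingularReport(z_star=z_star, convergent=convergent, ess=ess, valid=valid)


def integrate_canonical_equation(
    z0,
    cfg: ModelConfig,
    ad: ADConfig = ADConfig(),
    t_grid=None,
    t_max: float = 1e4,
    rtol: float = 1e-8,
):
    """Integrate ``dz/dt = m sigma^2 D(z)`` from ``z0``; returns (times, path).

    The path is clipped to the trait box by zeroing outward velocity at the
    boundary.  With all dimensions convergent stable the trajectory approaches
    z* monotonically along the gradient flow.
    """
    z0 = _check_domain(z0, cfg)
    z_hi = cfg.z_max

    def rhs(_t, z):
        zc = np.clip(z, 0.0, z_hi)
        v = ad.m * ad.sigma2 * selection_gradient(zc, cfg)
        v[(zc <= 0.0) & (v < 0.0)] = 0.0
        v[(zc >= z_hi) & (v > 0.0)] = 0.0
        return v

    if t_grid is None:
        t_grid = np.linspace(0.0, t_max, 200)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        z0,
        t_eval=t_grid,
        rtol=rtol,
        atol=1e-12,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"canonical-equation integration failed: {sol.message}")
    path = np.clip(sol.y.T, 0.0, z_hi)
    return sol.t, path


def _payoff_table(strains, cfg: ModelConfig) -> np.ndarray:
    """Matrix Pi[i, j] = payoff of strain i against strain j."""
    m = len(strains)
    pi = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            pi[i, j] = pairwise_payoff(strains[i], strains[j], cfg)
    return pi


def dimorphic_equilibrium(strain_a, strain_b, cfg: ModelConfig) -> DimorphicResident | None:
    """Protected-dimorphism frequency of ``strain_a`` against ``strain_b``.

    Requires mutual invasibility (each strain grows when rare in the other);
    returns None otherwise.  At equilibrium both strains earn the same mean
    payoff against the (p, 1-p) mixture, which for pairwise games is a linear
    condition in p.
    """
    a = _check_domain(strain_a, cfg)
    b = _check_domain(strain_b, cfg)
    if invasion_fitness(a, b, cfg) <= 0.0 or invasion_fitness(b, a, cfg) <= 0.0:
        return None
    pi = _payoff_table([a, b], cfg)
    # p*pi_aa + (1-p)*pi_ab = p*pi_ba + (1-p)*pi_bb
    denom = pi[0, 0] - pi[0, 1] - pi[1, 0] + pi[1, 1]
    if denom == 0.0:
        return None
    p = (pi[1, 1] - pi[0, 1]) / denom
    if not 0.0 < p < 1.0:
        return None
    return DimorphicResident(strain_a=a, strain_b=b, p=float(p))


def corner_invasion(resident: DimorphicResident, mutant, cfg: ModelConfig) -> float:
    """First-order invasion advantage of a mutant against a dimorphic resident.

    Returns the mutant's mean payoff against the resident mixture minus the
    residents' own mean payoff; a positive sign means the mutant initially
    spreads.
    """
    mut = _check_domain(mutant, cfg)
    p = resident.p
    w_mut = p * pairwise_payoff(mut, resident.strain_a, cfg) + (1.0 - p) * pairwise_payoff(
        mut, resident.strain_b, cfg
    )
    pi = _payoff_table([resident.strain_a, resident.strain_b], cfg)
    w_res_a = p * pi[0, 0] + (1.0 - p) * pi[0, 1]
    w_res_b = p * pi[1, 0] + (1.0 - p) * pi[1, 1]
    w_res = p * w_res_a + (1.0 - p) * w_res_b
    return float(w_mut - w_res)


def sample_random_game(
    rng: np.random.Generator,
    reference: GameParams = DEFAULT_GAME,
    max_tries: int = 100_000,
) -> GameParams:
    """Draw a random game with a branching point comparable to ``reference``.

    ``a, c ~ U(0, 5)``; curvatures are drawn around ``a1 b1 / a`` and
    ``c1 d1 / c`` (relative sd 0.1) so that the product terms, and hence the
    gradient and curvature scales near equilibrium, match the reference game.
    Draws are rejected until the singular point is convergent stable, not ESS,
    and strictly inside the trait box.
    """
    ab_ref = reference.a * reference.b
    cd_ref = reference.c * reference.d
    for _ in range(max_tries):
        a = rng.uniform(0.0, 5.0)
        c = rng.uniform(0.0, 5.0)
        if a <= 0.0 or c <= 0.0:
            continue
        b = rng.normal(ab_ref / a, 0.1 * ab_ref / a)
        d = rng.normal(cd_ref / c, 0.1 * cd_ref / c)
        if b <= 0.0 and d <= 0.0:
            continue
        game = GameParams(a=a, b=b, c=c, d=d)
        try:
            report = singular_strategy(ModelConfig(games=(game,)))
        except ValueError:
            continue
        if report.valid and report.classification == "branching_point":
            return game
    raise RuntimeError("rejection sampling failed to find a valid branching game")
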