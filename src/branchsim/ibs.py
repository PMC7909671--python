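"""Individual-based simulation of the multi-game continuous snowdrift model.

A fixed-size population of ``n`` individuals evolves in non-overlapping
generations.  Each generation every individual plays a configurable number of
explicit pairwise games against uniformly drawn partners (no self-pairing);
fitness is either a positive baseline plus the mean payoff (linear mapping)
or ``exp(mean payoff / T)`` (exponential mapping, the standard
strong-selection form; ``T`` is the selection temperature).  The next
generation is a fitness-proportional multinomial resample of size ``n``; each
offspring mutates with probability ``mu``, adding independent
Normal(0, sigma) deviates to every trait, clipped to the trait box.

The hot loop is JIT-compiled; the engine records the per-generation fitness
variance and trait mean/covariance series (used to locate the onset of
branching and to track the G-matrix orientation) and checks bimodality of the
population's leading-axis projection to detect completion of branching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .analysis import DIP_COMPLETION_THRESHOLD, projected_dip
from .games import ModelConfig

__all__ = [
    "IbsConfig",
    "Population",
    "IbsTrajectory",
    "default_baseline",
    "init_population",
    "advance_generation",
    "run_ibs",
    "SCALED_PRESET",
    "equilibrium_sd",
]


@dataclass(frozen=True)
class IbsConfig:
    """Engine parameters.

    ``sigma`` is the mutational standard deviation per trait, ``mu`` the
    per-offspring mutation probability.  ``baseline`` (None = automatic bound
    guaranteeing positive fitness) shifts payoffs into sampling weights.
    ``check_every`` sets both the completion-test cadence and the snapshot
    grid.
    """

    n: int = 1000
    sigma: float = 5e-4
    mu: float = 1e-2
    baseline: float | None = None
    fitness_mapping: str = "linear"  # or "exponential"
    selection_temperature: float = 0.02
    partners_per_round: int = 1
    check_every: int = 500
    store_snapshot_every: int | None = None
    max_generations: int = 1_500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sigma <= 0 or not 0.0 <= self.mu <= 1.0:
            raise ValueError("need sigma > 0 and mu in [0, 1]")
        if self.partners_per_round < 1:
            raise ValueError("need at least one partner per round")
        if self.fitness_mapping not in ("linear", "exponential"):
            raise ValueError("fitness_mapping must be 'linear' or 'exponential'")
        if self.selection_temperature <= 0:
            raise ValueError("selection_temperature must be positive")


#: desk-scale preset: exponential selection at temperature 0.015 makes
#: branching take off while directional selection still shapes the trait
#: cloud, so one replicate completes in ~40-80k generations (seconds).
SCALED_PRESET = IbsConfig(
    n=4000,
    sigma=5e-4,
    mu=1e-2,
    fitness_mapping="exponential",
    selection_temperature=0.015,
    check_every=500,
)


def equilibrium_sd(cfg: IbsConfig) -> float:
    """Mutation-drift equilibrium trait standard deviation ~ sqrt(n mu sigma^2)."""
    return float(np.sqrt(cfg.n * cfg.mu * cfg.sigma**2))


@dataclass
class Population:
    traits: np.ndarray  # (n, k)
    generation: int = 0
    fitness: np.ndarray | None = None


@dataclass
class IbsTrajectory:
    """Recorded output of one individual-based run.

    ``fitness_variance[g]``, ``mean_series[g]`` and ``cov_series[g]`` describe
    generation ``g + 1`` (the series start at generation 1).  ``cov_series``
    stores the upper triangle row-major: (0,0), (0,1), ..., (k-1,k-1).
    """

    fitness_variance: np.ndarray
    mean_series: np.ndarray
    cov_series: np.ndarray
    snapshots: list = field(default_factory=list)  # (generation, traits) pairs
    completion_generation: int | None = None
    completion_snapshot: np.ndarray | None = None
    final: Population | None = None
    k: int = 2

    def covariance_at(self, generation: int) -> np.ndarray:
        """Full covariance matrix recorded at a 1-based generation."""
        row = self.cov_series[generation - 1]
        k = self.k
        cov = np.empty((k, k))
        idx = 0
        for i in range(k):
            for j in range(i, k):
                cov[i, j] = cov[j, i] = row[idx]
                idx += 1
        return cov

    @property
    def n_generations(self) -> int:
        return len(self.fitness_variance)


_PCG_MULT = np.uint64(6364136223846793005)
_INV32 = 1.0 / 4294967296.0


@njit(cache=False, inline="always")
def _pcg_next(state):
    """PCG32 step: state in a length-2 uint64 array [state, inc]."""
    old = state[0]
    state[0] = old * _PCG_MULT + state[1]
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint64(old >> np.uint64(59))
    return np.uint32(
        (xorshifted >> np.uint32(rot)) | (xorshifted << np.uint32((-rot) & np.uint64(31)))
    )


@njit(cache=False, inline="always")
def _pcg_uniform(state):
    return float(_pcg_next(state)) * _INV32


@njit(cache=False)
def _run_generations(
    traits, zmax, ga, gb, gc, gd, scale, baseline, inv_temp, sigma, mu, partners,
    n_gens, seed, fitvar, meanz, covz,
):
    """Advance ``n_gens`` generations in place; returns -1 or the generation
    index at which a non-positive fitness appeared.

    ``inv_temp`` = 0 selects the linear mapping fitness = baseline + payoff;
    ``inv_temp`` > 0 the exponential mapping fitness = exp(payoff * inv_temp).
    Random numbers come from an inline PCG32 stream (reproducible from
    ``seed``); resampling uses Vose's alias method, so a generation costs
    O(n) with small constants.
    """
    state = np.empty(2, dtype=np.uint64)
    state[0] = np.uint64(0x853C49E6748FEA9B) ^ (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15))
    state[1] = np.uint64(0xDA3E39CB94B95BDB) | np.uint64(1)
    _pcg_next(state)
    _pcg_next(state)

    n, k = traits.shape
    fitness = np.empty(n)
    new_traits = np.empty_like(traits)
    # alias-method work arrays
    prob = np.empty(n)
    alias = np.empty(n, dtype=np.int64)
    small = np.empty(n, dtype=np.int64)
    large = np.empty(n, dtype=np.int64)
    # coefficient precomputation: payoff_d(x, t=x+x_j) = A1*t - A2*t^2 - C1*x + C2*x^2
    A1 = np.empty(k)
    A2 = np.empty(k)
    C1 = np.empty(k)
    C2 = np.empty(k)
    for d in range(k):
        A1[d] = scale[d] * ga[d]
        A2[d] = scale[d] * ga[d] * gb[d]
        C1[d] = scale[d] * gc[d]
        C2[d] = scale[d] * gc[d] * gd[d]
    inv_partners = 1.0 / partners
    have_norm = False
    spare_norm = 0.0

    for g in range(n_gens):
        # explicit pairwise interactions against uniform partners (no self)
        fsum = 0.0
        fsq = 0.0
        for i in range(n):
            acc = 0.0
            for _r in range(partners):
                j = np.int64((np.uint64(_pcg_next(state)) * np.uint64(n - 1)) >> np.uint64(32))
                if j >= i:
                    j += 1
                for d in range(k):
                    x = traits[i, d]
                    t = x + traits[j, d]
                    acc += A1[d] * t - A2[d] * t * t - C1[d] * x + C2[d] * x * x
            if inv_temp > 0.0:
                f = np.exp(acc * inv_partners * inv_temp)
            else:
                f = baseline + acc * inv_partners
                if f <= 0.0:
                    return g
            fitness[i] = f
            fsum += f
            fsq += f * f
        fitvar[g] = fsq / n - (fsum / n) ** 2
        # trait mean / covariance bookkeeping (series used post hoc)
        if k == 2:
            s0 = 0.0
            s1 = 0.0
            q00 = 0.0
            q01 = 0.0
            q11 = 0.0
            for i in range(n):
                a = traits[i, 0]
                b = traits[i, 1]
                s0 += a
                s1 += b
                q00 += a * a
                q01 += a * b
                q11 += b * b
            m0 = s0 / n
            m1 = s1 / n
            meanz[g, 0] = m0
            meanz[g, 1] = m1
            covz[g, 0] = q00 / n - m0 * m0
            covz[g, 1] = q01 / n - m0 * m1
            covz[g, 2] = q11 / n - m1 * m1
        else:
            for d in range(k):
                s = 0.0
                for i in range(n):
                    s += traits[i, d]
                meanz[g, d] = s / n
            idx = 0
            for d1 in range(k):
                for d2 in range(d1, k):
                    q = 0.0
                    for i in range(n):
                        q += traits[i, d1] * traits[i, d2]
                    covz[g, idx] = q / n - meanz[g, d1] * meanz[g, d2]
                    idx += 1
        # Vose alias table for fitness-proportional multinomial resampling
        ns = 0
        nl = 0
        inv_mean = n / fsum
        for i in range(n):
            p = fitness[i] * inv_mean
            prob[i] = p
            alias[i] = i
            if p < 1.0:
                small[ns] = i
                ns += 1
            else:
                large[nl] = i
                nl += 1
        while ns > 0 and nl > 0:
            ns -= 1
            s_i = small[ns]
            l_i = large[nl - 1]
            alias[s_i] = l_i
            prob[l_i] = prob[l_i] + prob[s_i] - 1.0
            if prob[l_i] < 1.0:
                nl -= 1
                small[ns] = l_i
                ns += 1
        # sample offspring, mutate at birth, clip to the trait box
        for i in range(n):
            u = _pcg_uniform(state) * n
            j = np.int64(u)
            if j >= n:
                j = n - 1
            if u - j >= prob[j]:
                j = alias[j]
            for d in range(k):
                new_traits[i, d] = traits[j, d]
            if _pcg_uniform(state) < mu:
                for d in range(k):
                    if have_norm:
                        have_norm = False
                        z = spare_norm
                    else:
                        # polar Box-Muller
                        while True:
                            v1 = 2.0 * _pcg_uniform(state) - 1.0
                            v2 = 2.0 * _pcg_uniform(state) - 1.0
                            rsq = v1 * v1 + v2 * v2
                            if 0.0 < rsq < 1.0:
                                break
                        fac = np.sqrt(-2.0 * np.log(rsq) / rsq)
                        z = v1 * fac
                        spare_norm = v2 * fac
                        have_norm = True
                    v = new_traits[i, d] + sigma * z
                    if v < 0.0:
                        v = 0.0
                    elif v > zmax[d]:
                        v = zmax[d]
                    new_traits[i, d] = v
        for i in range(n):
            for d in range(k):
                traits[i, d] = new_traits[i, d]
    return -1


def _model_arrays(model: ModelConfig):
    ga = np.array([g.a for g in model.games])
    gb = np.array([g.b for g in model.games])
    gc = np.array([g.c for g in model.games])
    gd = np.array([g.d for g in model.games])
    return ga, gb, gc, gd, model.scale.copy(), model.z_max.copy()


def default_baseline(model: ModelConfig) -> float:
    """1 plus a bound on |payoff|, guaranteeing positive sampling weights."""
    bound = 0.0
    for g, s in zip(model.games, model.scale):
        zm = g.z_max
        bound += s * max(abs(g.benefit(2.0 * zm)), abs(g.cost(zm)))
    return 1.0 + bound


def init_population(
    spec,
    cfg: IbsConfig,
    model: ModelConfig,
    rng: np.random.Generator | None = None,
) -> Population:
    """Create the founding population.

    ``spec`` is either a phenotype vector (point mass) or a ``(mean, cov)``
    pair for a multivariate-normal cloud; samples are clipped into the trait
    box.
    """
    k = model.k
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if isinstance(spec, tuple) and len(spec) == 2 and np.ndim(spec[1]) == 2:
        mean, cov = np.asarray(spec[0], float), np.asarray(spec[1], float)
        vals = np.linalg.eigvalsh(cov)
        if vals[0] < -1e-12:
            raise ValueError("covariance must be positive semidefinite")
        traits = rng.multivariate_normal(mean, cov, size=cfg.n, method="svd")
    else:
        traits = np.tile(np.asarray(spec, dtype=float), (cfg.n, 1))
    traits = np.clip(traits, 0.0, model.z_max)
    if traits.shape != (cfg.n, k):
        raise ValueError("initial spec incompatible with model dimension")
    return Population(traits=np.ascontiguousarray(traits), generation=0)


def advance_generation(
    pop: Population, cfg: IbsConfig, model: ModelConfig, rng: np.random.Generator
) -> Population:
    """One generation of interaction, selection, reproduction and mutation."""
    traits = pop.traits.copy()
    ga, gb, gc, gd, scale, zmax = _model_arrays(model)
    baseline = cfg.baseline if cfg.baseline is not None else default_baseline(model)
    fitvar = np.empty(1)
    meanz = np.empty((1, model.k))
    covz = np.empty((1, (model.k * (model.k + 1)) // 2))
    seed = int(rng.integers(0, 2**31 - 1))
    inv_temp = 0.0 if cfg.fitness_mapping == "linear" else 1.0 / cfg.selection_temperature
    bad = _run_generations(
        traits, zmax, ga, gb, gc, gd, scale, baseline, inv_temp, cfg.sigma, cfg.mu,
        cfg.partners_per_round, 1, seed, fitvar, meanz, covz,
    )
    if bad >= 0:
        raise ValueError(
            f"non-positive fitness encountered; increase baseline (now {baseline})"
        )
    return Population(traits=traits, generation=pop.generation + 1)


def run_ibs(
    cfg: IbsConfig,
    model: ModelConfig,
    init,
    *,
    stop_at_completion: bool = True,
    post_completion_generations: int = 0,
    detect_completion: bool = True,
    rng: np.random.Generator | None = None,
) -> IbsTrajectory:
    """Run the individual-based engine until branching completes (projected
    dip above the threshold) or ``max_generations``; fully seed-reproducible.

    ``init`` is passed to :func:`init_population`.  When
    ``post_completion_generations`` > 0 the run continues that many
    generations past completion (to reach the final evolutionary state).
    """
    k = model.k
    ss = np.random.SeedSequence(cfg.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    pop = init if isinstance(init, Population) else init_population(spec=init, cfg=cfg, model=model, rng=init_rng)
    traits = pop.traits.copy()
    ga, gb, gc, gd, scale, zmax = _model_arrays(model)
    baseline = cfg.baseline if cfg.baseline is not None else default_baseline(model)
    inv_temp = 0.0 if cfg.fitness_mapping == "linear" else 1.0 / cfg.selection_temperature
    ncov = (k * (k + 1)) // 2

    fitvar_chunks, mean_chunks, cov_chunks, snapshots = [], [], [], []
    completion_generation = None
    completion_snapshot = None
    gen = 0
    chunk_seeds = ss.spawn(1)[0].generate_state(
        int(np.ceil(cfg.max_generations / cfg.check_every))
        + int(np.ceil(post_completion_generations / cfg.check_every))
        + 2
    ) >> np.uint32(1)  # keep below 2**31
    chunk_idx = 0
    budget = cfg.max_generations
    while gen < budget:
        n_gens = int(min(cfg.check_every, budget - gen))
        fitvar = np.empty(n_gens)
        meanz = np.empty((n_gens, k))
        covz = np.empty((n_gens, ncov))
        bad = _run_generations(
            traits, zmax, ga, gb, gc, gd, scale, baseline, inv_temp, cfg.sigma, cfg.mu,
            cfg.partners_per_round, n_gens, int(chunk_seeds[chunk_idx]),
            fitvar, meanz, covz,
        )
        chunk_idx += 1
        if bad >= 0:
            raise ValueError(
                f"non-positive fitness at generation {gen + bad + 1}; "
                f"increase baseline (now {baseline})"
            )
        gen += n_gens
        fitvar_chunks.append(fitvar)
        mean_chunks.append(meanz)
        cov_chunks.append(covz)
        if cfg.store_snapshot_every and gen % cfg.store_snapshot_every == 0:
            snapshots.append((gen, traits.copy()))
        if completion_generation is None:
            # jitter at half the mutation step: clone atoms below the
            # mutational scale must not register as modes (the dip is
            # scale-free); deterministic via the chunk seed
            jit_rng = np.random.default_rng(int(chunk_seeds[chunk_idx - 1]) + 1)
            if projected_dip(traits, jitter=0.5 * cfg.sigma, rng=jit_rng) > DIP_COMPLETION_THRESHOLD:
                completion_generation = gen
                completion_snapshot = traits.copy()
                if stop_at_completion:
                    budget = gen + post_completion_generations
    final = Population(traits=traits.copy(), generation=gen)
    return IbsTrajectory(
        fitness_variance=np.concatenate(fitvar_chunks) if fitvar_chunks else np.empty(0),
        mean_series=np.vstack(mean_chunks) if mean_chunks else np.empty((0, k)),
        cov_series=np.vstack(cov_chunks) if cov_chunks else np.empty((0, ncov)),
        snapshots=snapshots,
        completion_generation=completion_generation,
        completion_snapshot=completion_snapshot,
        final=final,
        k=k,
    )
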