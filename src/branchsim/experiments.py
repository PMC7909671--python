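"""Reproducible ensemble drivers for the stochastic engines.

An :class:`ExperimentSpec` describes an initial-condition family (approach
from a given angle and distance, or starting at the branching point with a
correlated trait cloud), a replicate count and a master seed; replicate seeds
are spawned deterministically from the master seed.  ``run_ensemble`` returns
one row per replicate with full provenance (seed, parameters, measurements).
Replicates whose completion snapshot holds more than two branches are flagged
``kept = False`` and should be excluded from direction summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis
from .games import ModelConfig, singular_strategy
from .ibs import SCALED_PRESET, IbsConfig, equilibrium_sd, init_population, run_ibs
from .oss import OssConfig, run_oss

__all__ = ["ExperimentSpec", "generate_fixture_population", "run_ensemble", "replicate_seeds"]


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent 31-bit engine seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(c.generate_state(1)[0] >> np.uint32(1)) for c in ss.spawn(n)])


def generate_fixture_population(
    n: int,
    rho: float,
    sd: float,
    center,
    rng: np.random.Generator,
    z_max=None,
):
    """Bivariate-normal trait cloud with Pearson correlation ``rho``, clipped."""
    if not -1.0 < rho < 1.0:
        raise ValueError("need |rho| < 1")
    cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    pts = rng.multivariate_normal(np.asarray(center, float), cov, size=n, method="svd")
    if z_max is not None:
        pts = np.clip(pts, 0.0, z_max)
    return pts


@dataclass(frozen=True)
class ExperimentSpec:
    engine: str = "ibs"  # "ibs" or "oss"
    model: ModelConfig = field(default_factory=ModelConfig)
    ibs: IbsConfig = SCALED_PRESET
    oss: OssConfig = field(default_factory=OssConfig)
    approach_angles: tuple = (-3.0 * np.pi / 4.0,)
    approach_distance: float = 0.07
    rho: float | None = None  # when set, start at z* with a correlated cloud
    init_sd: float | None = None  # None: mutation-drift equilibrium sd
    replicates: int = 50
    master_seed: int = 0
    post_completion_generations: int = 0
    final_state: bool = False  # continue after completion until DOL/CD stable
    final_chunk: int = 25_000
    final_cap: int = 250_000
    pre_onset_lag: int = 100  # generations before onset at which G is read

    def __post_init__(self) -> None:
        if self.engine not in ("ibs", "oss"):
            raise ValueError("engine must be 'ibs' or 'oss'")
        if self.replicates < 0:
            raise ValueError("replicates must be nonnegative")


def _angles_3d_for_snapshot(traits, z0, z_star):
    try:
        axis = analysis.leading_eigenvector(analysis.g_matrix(traits))
        a = analysis.angles_3d(axis, z0, z_star)
    except ValueError:
        return None
    if np.isnan(a.phi) or np.isnan(a.psi):
        return None
    return a.phi, a.psi


def _run_ibs_replicate(spec: ExperimentSpec, angle, seed: int, z_star):
    cfg = replace(spec.ibs, seed=int(seed))
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)).spawn(1)[0])
    k = spec.model.k
    sd0 = spec.init_sd if spec.init_sd is not None else equilibrium_sd(cfg)
    if spec.rho is not None:
        from .ibs import Population

        traits = generate_fixture_population(
            cfg.n, spec.rho, sd0, z_star, rng, spec.model.z_max
        )
        pop = Population(traits=np.ascontiguousarray(traits))
        z0 = z_star.copy()
    else:
        if k == 2:
            z0 = z_star + spec.approach_distance * np.array(
                [np.cos(angle), np.sin(angle)]
            )
        else:
            # k = 3: approach along the main diagonal from below
            z0 = z_star - spec.approach_distance * np.ones(k) / np.sqrt(k)
        z0 = np.clip(z0, 0.0, spec.model.z_max)
        pop = init_population((z0, sd0**2 * np.eye(k)), cfg, spec.model, rng)
    traj = run_ibs(
        cfg,
        spec.model,
        pop,
        stop_at_completion=True,
        post_completion_generations=spec.post_completion_generations,
    )
    row = {
        "seed": int(seed),
        "approach_angle": np.nan if spec.rho is not None else float(angle),
        "rho": np.nan if spec.rho is None else float(spec.rho),
        "completion": np.nan,
        "onset": np.nan,
        "direction": np.nan,
        "g_orientation_pre_onset": np.nan,
        "n_branches": np.nan,
        "outcome": "",
        "kept": False,
        "phi": np.nan,
        "psi": np.nan,
    }
    if traj.completion_generation is None:
        return row
    comp = traj.completion_generation
    snap = traj.completion_snapshot
    nb = analysis.count_branches(snap)
    row["completion"] = comp
    row["n_branches"] = nb
    row["kept"] = nb <= 2
    onset = analysis.detect_onset(traj, comp)
    row["onset"] = onset
    pre = onset - spec.pre_onset_lag
    if k == 2:
        row["direction"] = analysis.branching_direction(snap)
        if pre >= 1:
            try:
                row["g_orientation_pre_onset"] = analysis.g_orientation(
                    traj.covariance_at(pre)
                )
            except ValueError:
                pass
    else:
        res = _angles_3d_for_snapshot(snap, z0, z_star)
        if res is None:
            row["kept"] = False
        else:
            row["phi"], row["psi"] = res
    if spec.final_state and k == 2:
        row["outcome"] = _evolve_to_final_state(spec, cfg, traj, z_star)
    elif spec.post_completion_generations > 0 and k == 2:
        row["outcome"] = _classify_final(traj.final.traits, z_star)
    return row


def _classify_final(traits, z_star) -> str:
    means = analysis.cluster_means(traits)
    if means.shape[0] < 2:
        return "UNRESOLVED"
    band = min(2.0 * float(np.sqrt(np.mean(np.var(traits, axis=0)))), 0.01)
    return analysis.classify_outcome(means, z_star, tol_band=band).label


def _evolve_to_final_state(spec: ExperimentSpec, cfg, traj, z_star) -> str:
    """Continue a completed run in chunks until the strain configuration
    settles into a stable DOL or CD quadrant pattern (or the cap is hit)."""
    from .ibs import Population

    pop = Population(traits=traj.final.traits.copy())
    label_prev = _classify_final(pop.traits, z_star)
    spent = 0
    while spent < spec.final_cap:
        cont_seed = int(
            np.random.SeedSequence((cfg.seed, 7_000_000 + spent)).generate_state(1)[0]
            >> np.uint32(1)
        )
        cont_cfg = replace(cfg, seed=cont_seed, max_generations=spec.final_chunk)
        t2 = run_ibs(cont_cfg, spec.model, pop, stop_at_completion=False,
                     detect_completion=False)
        pop = Population(traits=t2.final.traits.copy())
        spent += spec.final_chunk
        label = _classify_final(pop.traits, z_star)
        if label in ("DOL", "CD") and label == label_prev:
            return label
        label_prev = label
    return "UNRESOLVED" if label_prev not in ("DOL", "CD") else label_prev


def _run_oss_replicate(spec: ExperimentSpec, angle, seed: int, z_star):
    cfg = replace(spec.oss, seed=int(seed))
    z0 = z_star + spec.approach_distance * np.array([np.cos(angle), np.sin(angle)])
    z0 = np.clip(z0, 0.0, spec.model.z_max)
    res = run_oss(cfg, spec.model, z0)
    return {
        "seed": int(seed),
        "approach_angle": float(angle),
        "rho": np.nan,
        "completion": res.final.event_count if res.completed else np.nan,
        "onset": np.nan,
        "direction": res.direction if res.direction is not None else np.nan,
        "g_orientation_pre_onset": np.nan,
        "n_branches": len(res.final.strains),
        "outcome": "",
        "kept": res.completed and len(res.final.strains) <= 3,
        "phi": np.nan,
        "psi": np.nan,
    }


def run_ensemble(spec: ExperimentSpec) -> pd.DataFrame:
    """Run all replicates of an experiment; one provenance-rich row each.

    Replicate ``r`` uses approach angle ``approach_angles[r % len(angles)]``
    and a seed spawned from the master seed, so the table is reproducible and
    each replicate independent.
    """
    z_star = singular_strategy(spec.model).z_star
    seeds = replicate_seeds(spec.master_seed, spec.replicates)
    angles = spec.approach_angles
    rows = []
    for r in range(spec.replicates):
        angle = angles[r % len(angles)] if angles else np.nan
        try:
            if spec.engine == "ibs":
                row = _run_ibs_replicate(spec, angle, seeds[r], z_star)
            else:
                row = _run_oss_replicate(spec, angle, seeds[r], z_star)
        except Exception as exc:  # pragma: no cover - replicate crash guard
            row = {
                "seed": int(seeds[r]),
                "approach_angle": float(angle) if angle == angle else np.nan,
                "kept": False,
                "outcome": f"error: {exc}",
            }
        row["replicate"] = r
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df["engine"] = spec.engine
        df["master_seed"] = spec.master_seed
    return df
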