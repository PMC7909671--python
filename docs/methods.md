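# Methods

`branchsim` simulates evolutionary branching in populations that play several
continuous snowdrift games at once, and measures how the *direction* of
branching in multi-dimensional trait space depends on the population's recent
evolutionary history. This note records the model, the three engines, the
measurement conventions, the desk-scale parameter choices, and the places
where a genuinely open design decision had to be made.

## Model

An individual carries a trait vector `z = (z_1, …, z_k)`, the investment into
each of `k` public goods. A focal player `z'` meeting a partner `z` earns,
from good `i`,

    P_i(z_i', z_i) = B_i(z_i' + z_i) − C_i(z_i'),
    B_i(x) = a_i (x − b_i x²),   C_i(x) = c_i (x − d_i x²),

and the total payoff is `Σ_i k w_i P_i` with weights `w_i` summing to one
(uniform weights reproduce the plain per-game sum; for `k = 2` the asymmetric
case uses `w = (1 − α, α)`). Traits live in the box
`0 ≤ z_i ≤ min(1/(4 b_i), 1/(2 d_i))`, the range on which both functions
increase. The reference parameterization throughout is
`a = 1, b = 1.05, c = 0.9, d = 1.65`.

Adaptive-dynamics quantities are closed-form for quadratic games: invasion
fitness `w(z', z) = P(z', z) − P(z, z)`; selection gradient
`D_i(z) = k w_i [(a_i − c_i) − (4 a_i b_i − 2 c_i d_i) z_i]`; singular point
`z_i* = (a_i − c_i)/(4 a_i b_i − 2 c_i d_i)`; convergence stability iff
`4ab − 2cd > 0` and evolutionary stability iff `ab > cd`. The reference game
sits in the branching window `cd/2b < a < cd/b`: `z* ≈ 0.0813` is convergent
stable but a fitness minimum in every dimension, so the population first
converges to `z*` and then splits. Because payoffs are additive across goods
and the games interchangeable, the fitness landscape at `z*` is rotationally
symmetric: invasion fitness alone predicts no branching direction. The
package's central measurement is that the realized direction is set by the
shape of the trait distribution, which directional selection makes elongated
*perpendicular* to the direction of approach.

## Quantitative-genetics update

For a bivariate-normal cloud with covariance `G`, gradient `D` and landscape
curvature `γ` at the mean, one round of selection is modelled as

    G* = G + G (γ − 2 D Dᵀ) G,

which on a symmetric diagonal approach (`G = V I`, `γ = Γ I`, `D₁ = D₂ = D`)
gives diagonal `V + (Γ − 2D²)V²` and off-diagonal `−2D²V²`. The negative
covariance means the cloud loses variance along the direction of motion and
keeps it perpendicular — the mechanism behind perpendicular branching. The
gradient term here carries twice the weight it has in the classical
Lande–Arnold within-generation covariance update; the factor rescales the
magnitude of the directional-selection effect but changes neither the sign of
the induced covariance nor the post-selection orientation, and those are the
quantities the engines and the Gaussian-reweighting oracle test.

## Engines

**Individual-based (ibs).** Fixed size `n`, non-overlapping generations. Each
generation every individual plays `partners_per_round` explicit games against
uniformly drawn partners (no self-pairing); fitness maps the mean payoff
either linearly (`baseline + payoff`, the default; the baseline default is a
bound guaranteeing positivity) or exponentially (`exp(payoff / T)` with
selection temperature `T`). Reproduction is fitness-proportional multinomial
resampling (Vose alias method); each offspring mutates with probability `μ`,
adding independent `Normal(0, σ)` to every trait, clipped to the box.
Randomness comes from an inline PCG32 stream, so runs are bit-reproducible
from the seed. The engine records per-generation fitness variance and trait
mean/covariance series.

The exponential mapping exists because the linear mapping caps the selection
intensity at roughly (payoff range)/(mean fitness) ≈ 1. Under that cap the
take-off of branching at the fitness minimum is a rare drift event: the
incipient dimorphism waits far longer than the `~n`-generation memory of the
G-matrix, so the orientation built during the approach is forgotten before it
can seed the split. With `T` chosen so that `n Γ V / T ≳ 1`
(`V = n μ σ²` the standing variance), branching takes off while directional
selection still shapes the distribution — the regime in which the
distribution–selection feedback is observable at desk scale.

**Oligomorphic stochastic (oss).** A trait-substitution sequence over one to
six point strains at their equal-mean-payoff demographic equilibrium
(frequencies from a linear solve; strains with non-positive equilibrium
frequency are removed). Mutants arise from frequency-weighted parents with
`Normal(0, σ_oss)` displacement and are accepted with probability
`max(0, s)/s_scale`, `s` the invasion fitness against the current mixture
(linear branching-process approximation; `s_scale` defaults to three
mutational standard deviations times a bound on the gradient over the box).
An accepted mutant replaces its parent unless parent and mutant are mutually
invasible against the updated background, in which case both are retained —
that is branching. Completion: the set stays polymorphic for ten consecutive
successful invasions. Because the acceptance rule keeps only the uphill half
of the symmetric proposals, the monomorphic process follows the canonical
equation `dz/dt = m σ² D(z)` with `m = 1/(2 s_scale)` per proposal; a
regression test checks this slope. Proposals are screened in vectorized
batches; the resident state is constant between acceptances, so this is the
sequential process with a documented draw order.

**Deterministic density (pde).** The distribution over a `128 × 128` grid on
the trait box evolves by replicator dynamics with mutation at constant total
mass, `du/dt = M[f u] − f̄ u`, where `f` is the (baseline-shifted) mean
payoff of each phenotype against the current distribution — closed-form in
the marginal first and second moments for quadratic games — and
`M = (1 − μ) I + μ K` with `K` a truncated discrete Gaussian whose boundary
mass is renormalized back into the domain. Integration is adaptive explicit
Runge–Kutta in chunks, with bimodality of the marginals tested at chunk ends.

Two numerical guards matter. First, the mutation kernel is narrow
(`σ_kernel ≈ dx/2`, effectively nearest-neighbour mutation): in this game a
high-investment phenotype far from a low-investment resident is *fitter*
(the singular point is a fitness minimum), so a wide kernel lets the
population surf to the cooperative corner as a mutational front faster than
it branches locally. Second, cells holding less than `1e−13` of the total
mass are zeroed at inspection times: a deterministic equation otherwise lets
vanishingly small numerical tails nucleate distant fitter phenotypes, which
no finite population could do. The floor removes far less mass than the
`1e−6` conservation tolerance; measured drift is `~1e−9`. With per-source
boundary renormalization the kernel conserves mass exactly but does not hold
a uniform density exactly invariant near the walls; conservation was chosen
over wall-invariance.

## Measurements

* **Direction of approach**: angle of `z₀ − z*` in `(−π, π]`; bottom-left
  approaches are `−3π/4`.
* **G-matrix orientation / branching direction**: angle (mod π) of the
  leading eigenvector of the (frequency-weighted) trait covariance; the
  branching direction is this orientation at the completion snapshot.
* **Onset**: the generation with the lowest fitness variance, searched
  after the series' global maximum (variance peaks during the steep part of
  the approach; the guard avoids spurious minima while the founding
  population relaxes), excluding generation 1, up to completion.
* **Completion (ibs)**: first snapshot whose projection on the current
  leading covariance axis has Hartigan dip > 0.15. The projection receives
  `Normal(0, σ/2)` measurement jitter first (deterministic from the run
  seed): the dip is scale-free, so the handful of clonal lineages a finite
  population carries would otherwise register as spurious modes; genuinely
  diverged branches are many mutational steps apart and unaffected.
* **Completion (pde)**: a marginal has two local maxima, each at least ten
  times the minimum between them (after 3-cell smoothing; peaks below 5% of
  the marginal maximum are ignored as numerical ripples); the direction is
  the line through the two modes of the 2-D density, parabolic-refined.
* **Branch counting**: DBSCAN with `eps` = 3× the median positive
  nearest-neighbour distance, floored at half the RMS spread (the raw
  nearest-neighbour scale in a dense sample is far below the width of one
  branch and would shatter it), `min_pts = max(5, n/200)`. Replicates with
  more than two branches at completion are flagged and excluded from
  direction summaries.
* **Dip statistic**: computed exactly by modal-interval shrinkage over the
  empirical cdf's convex-minorant/concave-majorant hulls, in index space so
  that a point mass at the mode is free; validated against an independent
  linear-programming oracle built directly from the definition.
* **3-D angles**: for `k = 3`, plane Q contains the approach line and a
  fixed reference point; P is the perpendicular plane through `z*`;
  `I = P ∩ Q`. `φ` (`ψ`) is the angle between I and the branch line's
  projection on Q (P). The branch line — the leading covariance eigenvector
  at completion — is axial, so it is folded to a nonnegative I-component and
  mode estimates symmetrize each angle with its antipode; perpendicular
  branching puts the `φ` modes at 0 and π.
* **Outcomes**: quadrants around `z*`; occupancy `{(+,−),(−,+)}` is division
  of labor (DOL), `{(+,+),(−,−)}` cooperator–defector (CD); strains within a
  tolerance band (2 population standard deviations, capped at 0.01) of a
  dividing line are unclassifiable. Final-state runs continue after
  completion in 25k-generation chunks until the label is stably DOL or CD
  (cap 250k), else they count as unresolved.

## Desk-scale presets

The headline regime (`n = 10⁴`, `σ = 2.5 × 10⁻⁵`) needs on the order of 10⁶+
generations per replicate; the presets scale it down while preserving the
measured quantities, which are angles and discrete labels:

* `SCALED_PRESET` (2-D direction statistics, 3-D acceptance run):
  `n = 4000, σ = 5 × 10⁻⁴, μ = 10⁻²`, exponential selection `T = 0.015`,
  approach distance 0.07, founding cloud at the mutation–drift equilibrium
  standard deviation `√(n μ σ²) ≈ 3.2 × 10⁻³`. Keeps `√V/z* ≈ 4%` so the
  dip crosses its threshold while the two games are still coupled (at larger
  mutational variance the games desynchronize before detection and measured
  directions collapse onto the axes), and `n Γ V / T ≈ 1.7` so take-off is
  prompt. One replicate ≈ 30–80k generations (~8 s).
* `COARSE_PRESET` (outcome census, 3-D test): `n = 2000, σ = 7.07 × 10⁻⁴`
  (same `V`), half the cost per generation; used where the statistic is a
  label or an axial mode rather than a 0.2-radian mean.
* OSS runs at the printed `σ_oss = 1.5 × 10⁻³`; PDE at the defaults above.

What the synthetic conditions do *not* emulate: overlapping generations,
spatial or group structure, explicit demographic stochasticity in the oss
engine, sexual reproduction/recombination (clonal inheritance preserves the
linkage disequilibrium that couples the two games), and the adiabatic
`σ → 0` limit itself — at desk scale the branching direction is noticeably
stochastic around its modal value, so all directional claims are about
circular means and modes of replicate ensembles, not individual runs.

## Known limitations

* The ibs completion time inherits the chunk granularity (`check_every`).
* The dip-threshold rule cannot flag completion while branch sizes are more
  uneven than ~70/30 (an unbalanced two-atom distribution has dip
  `min(w, 1−w)/2`), which delays detection in strongly drifting replicates.
* The exponential-selection presets make late-stage divergence nearly
  deterministic; consequences of near-neutral co-existence dynamics at the
  corners (e.g. very long-lived three-strain transients) are under-sampled.
* The PDE engine is `k = 2` only; three-dimensional claims are tested by the
  individual-based engine.
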