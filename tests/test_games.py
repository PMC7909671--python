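"""Core game algebra: payoffs, invasion fitness, gradients, singular point,
canonical-equation trajectories and dimorphic-resident analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from branchsim.games import (
    ADConfig,
    DimorphicResident,
    DomainError,
    GameParams,
    ModelConfig,
    corner_invasion,
    dimorphic_equilibrium,
    integrate_canonical_equation,
    invasion_fitness,
    pairwise_payoff,
    sample_random_game,
    selection_gradient,
    singular_strategy,
)

BOX = st.floats(min_value=0.0, max_value=0.238, allow_nan=False)
INNER = st.floats(min_value=1e-3, max_value=0.237, allow_nan=False)


class TestPayoff:
    def test_zero_at_origin(self, model):
        assert pairwise_payoff([0, 0], [0, 0], model) == 0.0

    def test_printed_value(self, model):
        assert pairwise_payoff([0.1, 0.1], [0.1, 0.1], model) == pytest.approx(
            0.16570, abs=1e-9
        )

    def test_exchange_symmetry(self, model, rng):
        z1 = rng.uniform(0, 0.2, 2)
        z2 = rng.uniform(0, 0.2, 2)
        assert pairwise_payoff(z1, z2, model) == pytest.approx(
            pairwise_payoff(z1[::-1], z2[::-1], model), abs=1e-14
        )

    def test_domain_error(self, model):
        with pytest.raises(DomainError):
            pairwise_payoff([0.3, 0.1], [0.1, 0.1], model)

    def test_uniform_weights_reproduce_plain_sum(self):
        """k * w_i with uniform weights equals the unweighted per-game sum."""
        m_sum = ModelConfig()
        m_alpha = ModelConfig.asymmetric(0.5)
        z1, z2 = np.array([0.07, 0.11]), np.array([0.02, 0.16])
        assert pairwise_payoff(z1, z2, m_sum) == pytest.approx(
            pairwise_payoff(z1, z2, m_alpha), abs=1e-14
        )


class TestInvasionFitness:
    @settings(max_examples=50, deadline=None)
    @given(z1=BOX, z2=BOX)
    def test_self_invasion_is_zero(self, model, z1, z2):
        assert abs(invasion_fitness([z1, z2], [z1, z2], model)) < 1e-12

    def test_printed_value(self, model):
        assert invasion_fitness([0.1, 0.1], [0.05, 0.05], model) == pytest.approx(
            0.006025, abs=1e-9
        )

    def test_rotational_symmetry_at_singular_point(self, model, z_star):
        """All mutants equidistant from the resident at z* are equally fit."""
        eps = 1e-3
        vals = [
            invasion_fitness(z_star + eps * np.array([np.cos(a), np.sin(a)]), z_star, model)
            for a in np.linspace(0, 2 * np.pi, 9)
        ]
        assert np.ptp(vals) < 1e-12


class TestSelectionGradient:
    def test_at_origin(self, model):
        assert selection_gradient([0.0, 0.0], model) == pytest.approx([0.1, 0.1])

    def test_vanishes_at_singular_point(self, model, z_star):
        assert np.allclose(selection_gradient(z_star, model), 0.0, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(z1=INNER, z2=INNER)
    def test_matches_finite_differences(self, model, z1, z2):
        z = np.array([z1, z2])
        h = 1e-5
        grad = selection_gradient(z, model)
        for i in range(2):
            e = np.zeros(2)
            e[i] = h
            fd = (
                pairwise_payoff(z + e, z, model) - pairwise_payoff(z - e, z, model)
            ) / (2 * h)
            assert grad[i] == pytest.approx(fd, abs=1e-6)

    def test_linear_closed_form(self, model, rng):
        """D_i(z) = (a - c) - (4ab - 2cd) z_i for the plain-sum model."""
        z = rng.uniform(0, 0.2, 2)
        expected = 0.1 - 1.23 * z
        assert np.allclose(selection_gradient(z, model), expected, atol=1e-12)


class TestSingularStrategy:
    def test_reference_classification(self, model):
        rep = singular_strategy(model)
        assert rep.z_star == pytest.approx([0.081301, 0.081301], abs=1e-6)
        assert rep.convergent.all() and not rep.ess.any()
        assert rep.classification == "branching_point"
        assert rep.valid

    def test_branching_window_inequality(self):
        g = GameParams()
        assert g.c * g.d / (2 * g.b) == pytest.approx(0.70714, abs=1e-5)
        assert g.c * g.d / g.b == pytest.approx(1.41429, abs=1e-5)
        assert g.c * g.d / (2 * g.b) < g.a < g.c * g.d / g.b

    def test_trait_bound(self):
        assert GameParams().z_max == pytest.approx(0.238095, abs=1e-6)

    def test_matches_grid_search(self, model):
        """Brute-force search for the gradient zero agrees within resolution."""
        grid = np.linspace(1e-4, model.z_max[0] - 1e-4, 4001)
        vals = [abs(selection_gradient([z, z], model)[0]) for z in grid]
        z_grid = grid[int(np.argmin(vals))]
        assert abs(z_grid - singular_strategy(model).z_star[0]) < grid[1] - grid[0]

    def test_ess_attractor_classification(self):
        # cost curvature below benefit curvature: a > cd/b makes z* an ESS
        g = GameParams(a=2.0, b=1.05, c=0.9, d=1.65)
        rep = singular_strategy(ModelConfig(games=(g, g)))
        assert rep.classification == "ess_attractor"


class TestCanonicalEquation:
    def test_fixed_point(self, model, z_star):
        _, path = integrate_canonical_equation(z_star, model, t_max=50.0)
        assert np.allclose(path, z_star, atol=1e-9)

    def test_diagonal_approach_converges(self, model, z_star):
        t, path = integrate_canonical_equation([0.01, 0.01], model, t_max=2000.0)
        assert np.allclose(path[:, 0], path[:, 1], atol=1e-9)  # stays diagonal
        assert np.allclose(path[-1], z_star, atol=1e-6)

    def test_time_rescaling(self, model):
        """Halving m sigma^2 exactly doubles the clock."""
        t1 = np.linspace(0, 500, 40)
        _, p1 = integrate_canonical_equation([0.01, 0.02], model, ADConfig(m=1.0), t1)
        _, p2 = integrate_canonical_equation(
            [0.01, 0.02], model, ADConfig(m=0.5), 2.0 * t1
        )
        assert np.allclose(p1, p2, atol=1e-7)


class TestDimorphicResidents:
    def test_mirror_strains_balance(self, model):
        eq = dimorphic_equilibrium([0.2, 0.0], [0.0, 0.2], model)
        assert eq.p == pytest.approx(0.5, abs=1e-12)

    def test_printed_equilibrium(self, model):
        eq = dimorphic_equilibrium([0.0, 0.0], [0.2, 0.2], model)
        assert eq.p == pytest.approx(0.554762, abs=1e-6)

    def test_not_mutually_invasible(self, model, z_star):
        # two strains on the same uphill side: the higher one excludes the lower
        assert dimorphic_equilibrium([0.01, 0.01], [0.02, 0.02], model) is None

    def test_corner_invasion_dol_resident(self, model):
        dol = DimorphicResident(np.array([0.2, 0.0]), np.array([0.0, 0.2]), 0.5)
        assert corner_invasion(dol, [0.0, 0.0], model) == pytest.approx(0.0046, abs=1e-9)
        assert corner_invasion(dol, [0.2, 0.2], model) == pytest.approx(-0.0046, abs=1e-9)

    def test_corner_invasion_cd_resident_neutral(self, model):
        cd = dimorphic_equilibrium([0.0, 0.0], [0.2, 0.2], model)
        assert abs(corner_invasion(cd, [0.2, 0.0], model)) < 1e-12

    def test_corner_rule_across_random_games(self):
        """For symmetric DOL residents at the trait bound, the successful
        corner mutant is the defector iff z_max/2 > z*."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            g = sample_random_game(rng)
            m = ModelConfig.symmetric(g)
            rep = singular_strategy(m)
            h = g.z_max * (1.0 - 1e-9)
            eq = dimorphic_equilibrium([h, 0.0], [0.0, h], m)
            if eq is None:
                continue
            defector = corner_invasion(eq, [0.0, 0.0], m)
            cooperator = corner_invasion(eq, [h, h], m)
            if h / 2 > rep.z_star[0]:
                assert defector > 0 > cooperator
            else:
                assert cooperator > 0 > defector
            checked += 1


class TestRandomGameSampler:
    def test_accepted_draws_are_branching_points(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = sample_random_game(rng)
            rep = singular_strategy(ModelConfig(games=(g,)))
            assert rep.classification == "branching_point"
            assert 0 < rep.z_star[0] < g.z_max

    def test_acceptance_fraction_nontrivial(self):
        """The rejection sampler accepts some but not all raw draws."""
        rng = np.random.default_rng(1)
        ref = GameParams()
        accepted = 0
        total = 2000
        for _ in range(total):
            a, c = rng.uniform(0, 5), rng.uniform(0, 5)
            b = rng.normal(ref.a * ref.b / a, 0.1 * ref.a * ref.b / a)
            d = rng.normal(ref.c * ref.d / c, 0.1 * ref.c * ref.d / c)
            try:
                rep = singular_strategy(ModelConfig(games=(GameParams(a, b, c, d),)))
            except ValueError:
                continue
            if rep.valid and rep.classification == "branching_point":
                accepted += 1
        assert 0 < accepted < total


class TestCoordinatePermutation:
    @settings(max_examples=25, deadline=None)
    @given(z1=BOX, z2=BOX, w1=BOX, w2=BOX)
    def test_operations_commute_with_swap(self, model, z1, z2, w1, w2):
        zm, zr = np.array([z1, z2]), np.array([w1, w2])
        assert invasion_fitness(zm, zr, model) == pytest.approx(
            invasion_fitness(zm[::-1], zr[::-1], model), abs=1e-13
        )
        assert np.allclose(
            selection_gradient(zm, model)[::-1],
            selection_gradient(zm[::-1], model),
            atol=1e-13,
        )
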