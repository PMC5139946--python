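"""Invasion fitness, selection gradients, canonical-equation machinery."""

import numpy as np
import pytest

from twosex.adaptive import (
    MutantModel,
    canonical_rhs,
    detect_neutral_line,
    find_singular_strategy,
    integrate_strategy_trajectory,
    invasion_fitness,
    mutational_variance,
    selection_gradient,
    union_weighted_sex_ratio,
)
from twosex.core import TwoSexModelError, solve_equilibrium
from twosex.maternal_age import maternal_age_model
from twosex.maternal_quality import maternal_quality_model
from twosex.scenarios import generate_scenario
from twosex.strategy import SexRatioStrategy


def sex_symmetric_model():
    """Case 1a with every male rate equal to its female counterpart and
    equal offspring costs: exchanging the sexes is a model symmetry."""
    return maternal_age_model(k1=10, k2=10, Cm=0.5, Cf=0.5)


class TestMutantConstruction:
    @pytest.mark.parametrize("mode", ["literal", "expanded"])
    def test_self_invasion_neutrality(self, mode):
        """A mutant identical to the resident grows at the resident rate."""
        for case, seeds in (("case1a", range(4)), ("case2", range(4))):
            for seed in seeds:
                sc = generate_scenario(case, 300 + seed)
                model = sc.model()
                eq = solve_equilibrium(model, sc.strategy)
                lam_prime = MutantModel(model, sc.strategy, eq, mode).growth_rate(sc.strategy)
                assert abs(lam_prime - eq.lam) < 1e-8

    def test_expanded_dimensions(self):
        """Doubled union block: 6 singles + 8 unions = 14 stages (Case 1),
        8 singles + 8 unions = 16 stages (Case 2)."""
        m1 = maternal_age_model()
        s = SexRatioStrategy(0.5, 0.5)
        eq = solve_equilibrium(m1, s)
        assert MutantModel(m1, s, eq, "expanded").n_stages == 14
        m2 = maternal_quality_model()
        eq2 = solve_equilibrium(m2, s)
        assert MutantModel(m2, s, eq2, "expanded").n_stages == 16

    def test_unconverged_resident_rejected(self):
        model = maternal_age_model()
        s = SexRatioStrategy(0.5, 0.5)
        eq = solve_equilibrium(model, s)
        eq.residual = 1e-3
        with pytest.raises(TwoSexModelError):
            MutantModel(model, s, eq)


class TestInvasionFitness:
    def test_sign_toward_fisherian_line(self):
        """With equal maternal rates, a resident above the equal-investment
        sex ratio is invadable by mutants shifting s̄ back toward it."""
        model = maternal_age_model(k1=10, k2=10, Cm=0.4, Cf=0.6)
        resident = SexRatioStrategy(0.68, 0.68)
        eq = solve_equilibrium(model, resident)
        assert invasion_fitness(model, resident, eq, SexRatioStrategy(0.64, 0.64)) > 0
        assert invasion_fitness(model, resident, eq, SexRatioStrategy(0.72, 0.72)) < 0

    def test_first_order_antisymmetry(self):
        """Λ(s→s′) ≈ −Λ(s′→s) for small mutant steps."""
        model = maternal_age_model(k1=10, k2=10, Cm=0.4, Cf=0.6)
        a = SexRatioStrategy(0.5, 0.5)
        b = SexRatioStrategy(0.503, 0.499)
        eq_a = solve_equilibrium(model, a)
        eq_b = solve_equilibrium(model, b)
        lam_ab = invasion_fitness(model, a, eq_a, b)
        lam_ba = invasion_fitness(model, b, eq_b, a)
        assert abs(lam_ab + lam_ba) < 0.2 * abs(lam_ab) + 1e-9


class TestSelectionGradient:
    def test_sex_symmetric_stationary_point(self):
        """Exchange symmetry of the sexes forces D = 0 at s = (0.5, 0.5)."""
        model = sex_symmetric_model()
        s = SexRatioStrategy(0.5, 0.5)
        eq = solve_equilibrium(model, s)
        for mode in ("literal", "expanded"):
            D = selection_gradient(model, s, eq, mode=mode).D
            assert np.max(np.abs(D)) < 1e-8

    def test_gradient_vanishes_on_neutral_line(self):
        """At a trajectory endpoint on the Case-1a neutral line both gradient
        components vanish and the average sex ratio is the Fisherian value."""
        model = maternal_age_model(k1=10, k2=10, Cm=0.4, Cf=0.6)
        traj = integrate_strategy_trajectory(model, SexRatioStrategy(0.35, 0.75))
        assert np.max(np.abs(traj.gradient_at_end)) < 1e-6
        assert traj.s_bar_at_end == pytest.approx(0.6, abs=0.01)

    def test_methods_cross_agreement(self):
        """Central finite differences and the eigen-sensitivity (vec) formula
        agree on the gradient across random scenarios."""
        for case, n in (("case1a", 10), ("case2", 10)):
            for seed in range(n):
                sc = generate_scenario(case, 500 + seed)
                model = sc.model()
                eq = solve_equilibrium(model, sc.strategy)
                D_fd = selection_gradient(model, sc.strategy, eq, method="finite-difference").D
                D_vec = selection_gradient(model, sc.strategy, eq, method="vec-formula").D
                scale = max(np.max(np.abs(D_fd)), np.max(np.abs(D_vec)))
                # identically-zero gradients (degenerate scenarios) agree by
                # definition; 1e-9 is the finite-difference noise floor
                assert np.max(np.abs(D_fd - D_vec)) < 1e-4 * scale + 1e-9

    def test_unknown_method_rejected(self, case1a_equal_model, case1a_equal_eq):
        s, eq = case1a_equal_eq
        with pytest.raises(ValueError):
            selection_gradient(case1a_equal_model, s, eq, method="autodiff")


class TestCanonicalEquation:
    def test_variance_vanishes_on_boundary(self):
        D = np.array([3.0, -2.0])
        rhs = canonical_rhs(SexRatioStrategy(0.0, 0.5), D)
        assert rhs[0] == 0.0
        assert rhs[1] == pytest.approx(-0.5)

    def test_midpoint_arithmetic(self):
        D = np.array([1.0, -1.0])
        np.testing.assert_allclose(
            canonical_rhs(SexRatioStrategy(0.5, 0.5), D), [0.25, -0.25]
        )

    def test_interior_sign_agreement(self, rng):
        for _ in range(50):
            s = SexRatioStrategy(*rng.uniform(0.05, 0.95, 2))
            D = rng.standard_normal(2)
            rhs = canonical_rhs(s, D)
            assert np.all(np.sign(rhs) == np.sign(D))

    def test_variance_matrix_bounds(self, rng):
        for _ in range(50):
            V = mutational_variance(SexRatioStrategy(*rng.random(2)))
            assert V[0, 1] == V[1, 0] == 0.0
            assert 0 <= V[0, 0] <= 0.25 and 0 <= V[1, 1] <= 0.25


class TestTrajectories:
    def test_symmetric_stationary_start_stays_put(self):
        model = sex_symmetric_model()
        traj = integrate_strategy_trajectory(model, SexRatioStrategy(0.5, 0.5))
        assert traj.converged
        assert traj.endpoint.s1 == pytest.approx(0.5, abs=1e-6)
        assert traj.endpoint.s2 == pytest.approx(0.5, abs=1e-6)

    def test_unique_attractor_and_box_confinement(self):
        """With unequal maternal rates all starts reach the same boundary SS;
        no trajectory ever leaves the unit box."""
        model = maternal_age_model(k1=5, k2=15, Cm=0.4, Cf=0.6)
        report = detect_neutral_line(
            model,
            starts=[
                SexRatioStrategy(0.2, 0.3),
                SexRatioStrategy(0.5, 0.5),
                SexRatioStrategy(0.8, 0.3),
                SexRatioStrategy(0.3, 0.8),
                SexRatioStrategy(0.7, 0.7),
            ],
        )
        assert not report.is_neutral_line
        assert report.max_pairwise_distance < 1e-3
        for s in report.endpoints:
            assert 0.0 <= s.s1 <= 1.0 and 0.0 <= s.s2 <= 1.0

    def test_boundary_start_rejected(self, case1a_equal_model):
        with pytest.raises(ValueError):
            integrate_strategy_trajectory(case1a_equal_model, SexRatioStrategy(0.0, 0.5))


class TestSingularStrategySearch:
    def test_boundary_type4_resists_invasion_off_the_boundary(self):
        """At a Type-4 SS the gradient points out of the box: mutants with
        s1 > 0 cannot invade."""
        model = maternal_age_model(k1=5, k2=15, Cm=0.4, Cf=0.6)
        report = find_singular_strategy(model)
        assert report.ss_type == 4
        assert report.location.s1 == 0.0
        assert report.gradient_at_ss[0] < -1e-7
        eq = solve_equilibrium(model, report.location)
        mutant = SexRatioStrategy(0.02, report.location.s2)
        assert invasion_fitness(model, report.location, eq, mutant) < 0

    def test_interior_type1_in_symmetric_case2(self):
        model = maternal_quality_model(R1=15, R2=15, c1=0.5)
        report = find_singular_strategy(model)
        assert report.ss_type == 1
        assert report.location.s1 == pytest.approx(0.5, abs=1e-4)
        assert report.location.s2 == pytest.approx(0.5, abs=1e-4)
        assert np.max(np.abs(report.gradient_at_ss)) < 1e-8

    def test_report_serialization(self):
        model = maternal_quality_model(R1=15, R2=15, c1=0.5)
        report = find_singular_strategy(model)
        d = report.to_dict()
        assert d["found"] and d["ss_type"] == 1
        assert "interior" in report.summary()
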