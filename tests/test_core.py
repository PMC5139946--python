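"""Projection assembly, frequency dynamics, and equilibrium extraction."""

import numpy as np
import pytest

from twosex.core import (
    ConvergenceError,
    PopulationComposition,
    RateMatrixSet,
    StageSpace,
    TwoSexModel,
    assemble_projection,
    dominant_eigen_triple,
    frequency_rhs,
    solve_equilibrium,
)
from twosex.maternal_age import CASE1_STAGES, Case1Parameters, maternal_age_model
from twosex.scenarios import generate_scenario
from twosex.strategy import SexRatioStrategy


def transcribed_case1_projection(s1, s2, p, k1=10.0, k2=10.0, Cm=0.4, Cf=0.6, beta=0.2):
    """Oracle: literal entry-by-entry transcription of the printed Case-1
    birth, union and transition matrices, independent of the builders."""
    d = 0.1
    mu_m0 = mu_m1 = mu_m2 = mu_f0 = mu_f1 = mu_f2 = 0.1
    am1 = am2 = af1 = af2 = 0.5
    m0, m1, m2, f0, f1, f2, u11, u21, u12, u22 = p
    g1 = beta * k1 * (s1 * Cm + (1 - s1) * Cf)
    g2 = beta * k2 * (s2 * Cm + (1 - s2) * Cf)
    B = np.zeros((10, 10))
    B[0, 6] = B[0, 7] = s1 * k1
    B[0, 8] = B[0, 9] = s2 * k2
    B[3, 6] = B[3, 7] = (1 - s1) * k1
    B[3, 8] = B[3, 9] = (1 - s2) * k2
    m, f = m1 + m2, f1 + f2
    Um11 = Um21 = 2 * f1 / (m + f)
    Um12 = Um22 = 2 * f2 / (m + f)
    Uf11 = Uf12 = 2 * m1 / (m + f)
    Uf21 = Uf22 = 2 * m2 / (m + f)
    U = np.zeros((10, 10))
    U[1, 1] = -(Um11 + Um12)
    U[2, 2] = -(Um21 + Um22)
    U[4, 4] = -(Uf11 + Uf21)
    U[5, 5] = -(Uf12 + Uf22)
    U[6, 1], U[6, 4] = 0.5 * Um11, 0.5 * Uf11
    U[7, 2], U[7, 4] = 0.5 * Um21, 0.5 * Uf21
    U[8, 1], U[8, 5] = 0.5 * Um12, 0.5 * Uf12
    U[9, 2], U[9, 5] = 0.5 * Um22, 0.5 * Uf22
    T = np.zeros((10, 10))
    T[0, 0] = -(mu_m0 + am1)
    T[1, 0] = am1
    T[1, 1] = -(mu_m1 + am2)
    T[2, 1] = am2
    T[2, 2] = -mu_m2
    T[3, 3] = -(mu_f0 + af1)
    T[4, 3] = af1
    T[4, 4] = -(mu_f1 + af2)
    T[5, 4] = af2
    T[5, 5] = -mu_f2
    T[1, 6] = mu_f1 + g1 + d
    T[1, 8] = mu_f2 + g2 + d
    T[2, 7] = mu_f1 + g1 + d
    T[2, 9] = mu_f2 + g2 + d
    T[4, 6] = mu_m1 + g1 + d
    T[4, 7] = mu_m2 + g1 + d
    T[5, 8] = mu_m1 + g2 + d
    T[5, 9] = mu_m2 + g2 + d
    T[6, 6] = -(mu_m1 + mu_f1 + 2 * g1 + d + am2 + af2)
    T[7, 6] = am2
    T[7, 7] = -(mu_m2 + mu_f1 + 2 * g1 + d + af2)
    T[8, 6] = af2
    T[8, 8] = -(mu_m1 + mu_f2 + 2 * g2 + d + am2)
    T[9, 7] = af2
    T[9, 8] = am2
    T[9, 9] = -(mu_m2 + mu_f2 + 2 * g2 + d)
    return (T + B + U) / 3.0


class TestAssembleProjection:
    def test_zero_and_scaling(self):
        Z = np.zeros((4, 4))
        assert np.all(assemble_projection(RateMatrixSet(Z, Z, Z)) == 0.0)
        A = assemble_projection(RateMatrixSet(3 * np.eye(4), Z, Z))
        np.testing.assert_allclose(A, np.eye(4))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RateMatrixSet(np.zeros((3, 3)), np.zeros((4, 4)), np.zeros((4, 4)))

    def test_case1_matches_hand_transcription(self):
        """Builder output equals a literal transcription of the printed
        matrices, entry by entry, at uniform frequencies and s = (0.5, 0.5)."""
        model = maternal_age_model(k1=10, k2=10, Cm=0.4, Cf=0.6)
        s = SexRatioStrategy(0.5, 0.5)
        p = np.full(10, 0.1)
        A = model.projection(s, p)
        np.testing.assert_allclose(
            A, transcribed_case1_projection(0.5, 0.5, p), atol=1e-15
        )


class TestFrequencyRHS:
    def test_simplex_conservation_over_random_draws(self, rng):
        """The simplex projector kills growth along 1: |1ᵀ dp/dt| < 1e-12."""
        count = 0
        for case in ("case1a", "case1b", "case2"):
            for seed in range(334):
                sc = generate_scenario(case, seed)
                model = sc.model()
                p = rng.dirichlet(np.ones(model.stage_space.n))
                rhs = frequency_rhs(model, sc.strategy, p)
                assert abs(rhs.sum()) < 1e-12
                count += 1
        assert count >= 1000

    def test_negative_composition_rejected(self, case1a_equal_model):
        p = np.full(10, 0.1)
        p[0] = -0.1
        with pytest.raises(ValueError):
            frequency_rhs(case1a_equal_model, SexRatioStrategy(0.5, 0.5), p)

    def test_fixed_point_property(self, case1a_equal_model, case1a_equal_eq):
        s, eq = case1a_equal_eq
        rhs = frequency_rhs(case1a_equal_model, s, eq.p_hat.values)
        assert np.max(np.abs(rhs)) < 1e-8

    def test_frequency_independent_model_converges_to_eigenvector(self, rng):
        """With constant matrices the frequency flow converges to the dominant
        right eigenvector (oracle: direct eigendecomposition)."""
        space = StageSpace(
            labels=("a", "b", "c"),
            roles=("male-juvenile", "male-adult", "female-adult"),
            union_partners={},
        )
        M = rng.random((3, 3)) + np.diag(-2 * np.ones(3))
        rates = RateMatrixSet(T=3 * M, B=np.zeros((3, 3)), U=np.zeros((3, 3)))
        model = TwoSexModel(space, None, lambda s, p: rates, name="constant")
        eq = solve_equilibrium(model, None)
        _, w, _ = dominant_eigen_triple(M)
        np.testing.assert_allclose(eq.p_hat.values, w, atol=1e-8)


class TestSolveEquilibrium:
    def test_w_equals_p_hat(self):
        """The stable stage distribution is the right eigenvector: w = p̂."""
        model = maternal_age_model(k1=10, k2=10, Cm=0.4, Cf=0.6)
        eq = solve_equilibrium(model, SexRatioStrategy(0.6, 0.6))
        assert np.max(np.abs(eq.w - eq.p_hat.values)) < 1e-6
        assert abs(eq.v @ eq.w - 1.0) < 1e-10
        assert eq.residual < 1e-8

    def test_eigen_residuals(self, case1a_equal_eq):
        _, eq = case1a_equal_eq
        assert np.max(np.abs(eq.A @ eq.w - eq.lam * eq.w)) < 1e-8
        assert np.max(np.abs(eq.v @ eq.A - eq.lam * eq.v)) < 1e-8

    def test_multistart_uniqueness(self, case1a_equal_model, rng):
        """Different interior starts give the same growth rate."""
        s = SexRatioStrategy(0.4, 0.7)
        lams = []
        for _ in range(3):
            p0 = rng.dirichlet(np.ones(10))
            lams.append(solve_equilibrium(case1a_equal_model, s, p0=p0).lam)
        assert max(lams) - min(lams) < 1e-8

    def test_random_scenarios_have_real_dominant_eigenvalue(self):
        """Essential nonnegativity forces a real Perron root at equilibrium."""
        for case, n_seeds in (("case1a", 6), ("case2", 6)):
            for seed in range(n_seeds):
                sc = generate_scenario(case, 200 + seed)
                eq = solve_equilibrium(sc.model(), sc.strategy)
                assert np.isreal(eq.lam)
                assert eq.residual < 1e-8

    def test_no_female_production_degenerates_to_male_chain(self):
        """All-male births with no females left: the population collapses onto
        the slowest-decaying male stage, λ = −μ_m2 / 3."""
        model = maternal_age_model(k1=10, k2=10, Cm=0.4, Cf=0.6)
        p0 = np.array([0.2, 0.3, 0.3, 0.05, 0.05, 0.05, 0.0125, 0.0125, 0.0125, 0.0125])
        eq = solve_equilibrium(model, SexRatioStrategy(1.0, 1.0), p0=p0)
        assert eq.lam == pytest.approx(-0.1 / 3.0, abs=1e-8)

    def test_zero_mass_start_rejected(self, case1a_equal_model):
        with pytest.raises(ValueError):
            solve_equilibrium(case1a_equal_model, SexRatioStrategy(0.5, 0.5), p0=np.zeros(10))


class TestUnionBookkeeping:
    def test_formation_flows_match_total_mating_rate(self, rng):
        """Inflow to union uij equals Mij; the outflows from mi and fj
        attributable to that union each equal Mij."""
        from twosex.maternal_age import mating_rates_case1

        for seed in range(50):
            sc = generate_scenario("case1a", seed)
            model = sc.model()
            p = rng.dirichlet(np.ones(10)) + 0.01
            p = p / p.sum()
            rates = model.build_rates(sc.strategy, p)
            per_capita = mating_rates_case1(p)
            idx = {lab: i for i, lab in enumerate(CASE1_STAGES.labels)}
            for u, (ms, fs) in CASE1_STAGES.union_partners.items():
                i, j = idx[ms], idx[fs]
                um, uf = per_capita[u]
                M = um * p[i]
                assert uf * p[j] == pytest.approx(M, abs=1e-12)
                inflow = rates.U[idx[u], i] * p[i] + rates.U[idx[u], j] * p[j]
                assert inflow == pytest.approx(M, abs=1e-12)

    def test_individual_count_conservation(self, rng):
        """With unions weighted as two individuals, union formation conserves
        individuals: zᵀU = 0 column-wise."""
        for case in ("case1a", "case2"):
            sc = generate_scenario(case, 7)
            model = sc.model()
            p = rng.dirichlet(np.ones(model.stage_space.n))
            rates = model.build_rates(sc.strategy, p)
            rates.validate(model.stage_space)

    def test_structure_validation_catches_negative_birth(self):
        rates = RateMatrixSet(np.zeros((2, 2)), -np.eye(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            rates.validate()


class TestPopulationComposition:
    def test_roundoff_clamp_and_renormalize(self):
        pc = PopulationComposition(np.array([0.5, 0.5, -1e-13]))
        assert pc.values[2] == 0.0
        assert abs(pc.values.sum() - 1.0) < 1e-12

    def test_larger_negative_rejected(self):
        with pytest.raises(ValueError):
            PopulationComposition(np.array([0.5, 0.6, -1e-6]))
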