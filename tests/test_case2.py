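"""Maternal-quality (Trivers-Willard) case study."""

import copy

import numpy as np
import pytest

from twosex.core import solve_equilibrium
from twosex.maternal_quality import (
    CASE2_STAGES,
    Case2Parameters,
    build_rates_case2,
    equal_investment_check,
    maternal_quality_model,
    mating_rates_case2,
    reproductive_value_ratios,
    trivers_willard_classification,
)
from twosex.adaptive import SingularStrategyReport, find_singular_strategy
from twosex.strategy import SexRatioStrategy


def _symmetric_params():
    """Fully quality-symmetric: equal competitiveness, investment, mortality,
    and uninformative quality inheritance."""
    return Case2Parameters(R1=15.0, R2=15.0, c1=0.5, q=0.5)


class TestBuildRates:
    def test_birth_columns_sum_to_fertility(self, rng):
        """Every birth is some sex × some quality: each union's B column sums
        to the maternal fertility kj."""
        params = Case2Parameters(R1=10, R2=20, c1=0.2, q=0.7)
        s = SexRatioStrategy(0.35, 0.75)
        rates = build_rates_case2(params, s, np.full(12, 1 / 12))
        idx = {lab: i for i, lab in enumerate(CASE2_STAGES.labels)}
        for u, kj in (("u11", 10.0), ("u21", 10.0), ("u12", 20.0), ("u22", 20.0)):
            assert rates.B[:, idx[u]].sum() == pytest.approx(kj, rel=1e-12)

    def test_generic_mating_composition_matches_closed_forms(self, rng):
        """Biased female choice through the harmonic mean reproduces the
        closed forms, e.g. Uf21 = 2 c2 m2 / (c1 m1 + c2 (f + m2))."""
        for _ in range(200):
            c1 = rng.uniform(0.05, 0.5)
            params = Case2Parameters(c1=c1)
            c2 = 1 - c1
            p = rng.dirichlet(np.ones(12))
            m1, m2, f1, f2 = p[2], p[3], p[6], p[7]
            f = f1 + f2
            den1 = c1 * (f + m1) + c2 * m2
            den2 = c1 * m1 + c2 * (f + m2)
            rates = mating_rates_case2(params, p)
            assert rates["u11"][0] == pytest.approx(2 * c1 * f1 / den1, abs=1e-12)
            assert rates["u11"][1] == pytest.approx(2 * c1 * m1 / den1, abs=1e-12)
            assert rates["u21"][1] == pytest.approx(2 * c2 * m2 / den2, abs=1e-12)
            assert rates["u22"][0] == pytest.approx(2 * c2 * f2 / den2, abs=1e-12)

    def test_equal_competitiveness_collapses_to_random_mating(self, rng):
        """c1 = c2 reduces the biased forms to 2fj/(m+f), 2mi/(m+f)."""
        params = Case2Parameters(c1=0.5)
        for _ in range(100):
            p = rng.dirichlet(np.ones(12))
            tot = p[2] + p[3] + p[6] + p[7]
            rates = mating_rates_case2(params, p)
            for i, mi in ((1, p[2]), (2, p[3])):
                for j, fj in ((1, p[6]), (2, p[7])):
                    um, uf = rates[f"u{i}{j}"]
                    assert um == pytest.approx(2 * fj / tot, abs=1e-12)
                    assert uf == pytest.approx(2 * mi / tot, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Case2Parameters(c1=0.7)  # biased requires c1 <= 0.5
        with pytest.raises(ValueError):
            Case2Parameters(q=0.3)  # inheritance requires q >= 0.5

    def test_no_union_type_transitions(self):
        """Adults never change quality, so union columns have no
        union-to-union flows."""
        rates = build_rates_case2(
            Case2Parameters(), SexRatioStrategy(0.5, 0.5), np.full(12, 1 / 12)
        )
        unions = slice(8, 12)
        off = rates.T[unions, unions] - np.diag(np.diag(rates.T[unions, unions]))
        assert np.all(off == 0)


class TestReproductiveValueRatios:
    def test_quality_symmetric_model_has_unit_ratios(self):
        model = maternal_quality_model(_symmetric_params())
        eq = solve_equilibrium(model, SexRatioStrategy(0.5, 0.5))
        rvr = reproductive_value_ratios(eq)
        assert rvr.MRVR == pytest.approx(1.0, abs=1e-9)
        assert rvr.FRVR == pytest.approx(1.0, abs=1e-9)
        assert rvr.verdict == "MRVR=FRVR"

    def test_rescaling_invariance(self):
        model = maternal_quality_model(R1=10, R2=20, c1=0.2)
        eq = solve_equilibrium(model, SexRatioStrategy(0.4, 0.7))
        rvr = reproductive_value_ratios(eq)
        eq_scaled = copy.deepcopy(eq)
        eq_scaled.v = 3.7 * eq_scaled.v
        rvr2 = reproductive_value_ratios(eq_scaled)
        assert rvr2.MRVR == pytest.approx(rvr.MRVR, rel=1e-14)
        assert rvr2.FRVR == pytest.approx(rvr.FRVR, rel=1e-14)


class TestTriversWillardClassification:
    @pytest.mark.parametrize(
        "ss_type, mrvr, frvr, consistent",
        [
            (3, 2.0, 1.1, True),
            (4, 2.0, 1.1, True),
            (2, 0.9, 1.5, True),
            (5, 0.9, 1.5, True),
            (1, 1.0, 1.0, True),
            (3, 0.9, 1.5, False),
        ],
    )
    def test_table_correspondence(self, ss_type, mrvr, frvr, consistent):
        ss = SingularStrategyReport(
            location=SexRatioStrategy(0.5, 0.5),
            ss_type=ss_type,
            gradient_at_ss=np.zeros(2),
        )
        from twosex.maternal_quality import RVRReport

        rvr = RVRReport(
            v_m01=1.0,
            v_m02=mrvr,
            v_f01=1.0,
            v_f02=frvr,
            MRVR=mrvr,
            FRVR=frvr,
            verdict="MRVR=FRVR"
            if abs(mrvr - frvr) <= 1e-3 * max(mrvr, frvr)
            else ("MRVR>FRVR" if mrvr > frvr else "MRVR<FRVR"),
        )
        out = trivers_willard_classification(ss, rvr)
        assert out["consistent"] is consistent


class TestEqualInvestment:
    def test_symmetric_model_residuals_vanish(self):
        """Fully sex- and quality-symmetric model at s = (0.5, 0.5): the cost
        ratio equals both juvenile reproductive-value ratios exactly."""
        model = maternal_quality_model(_symmetric_params())
        eq = solve_equilibrium(model, SexRatioStrategy(0.5, 0.5))
        ss = SingularStrategyReport(
            location=SexRatioStrategy(0.5, 0.5), ss_type=1, gradient_at_ss=np.zeros(2)
        )
        out = equal_investment_check(ss, eq, Cm=1.0, Cf=1.0)
        assert out["applicable"]
        assert out["residual_low"] < 1e-9
        assert out["residual_high"] < 1e-9

    def test_boundary_ss_reports_inequalities(self):
        model = maternal_quality_model(R1=15, R2=15, c1=0.1)
        ss = find_singular_strategy(model)
        assert ss.ss_type == 3
        eq = solve_equilibrium(model, ss.location)
        out = equal_investment_check(ss, eq, Cm=1.0, Cf=1.0)
        assert not out["applicable"]
        assert out["inequalities_hold"]
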