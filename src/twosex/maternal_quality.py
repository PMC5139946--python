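"""Case study 2 — sex ratios that depend on maternal quality (Trivers-Willard).

Twelve stages: low/high-quality juveniles of each sex (m01, m02, f01, f02),
low/high-quality adults (m1, m2, f1, f2), and four union types.  Quality is
set at birth by maternal transmission (a quality-``j`` mother produces
quality-``i`` offspring with probability ``q_ij``) and never changes within a
lifetime.  High quality can confer two advantages: male competitiveness in
mating (``c2 > c1``, females prefer high-quality males) and female resource
investment (``R2 > R1``, higher fertility through equal investment).

The "variance in reproductive success" of each sex is operationalized as the
ratio of high- to low-quality juvenile reproductive values (MRVR for males,
FRVR for females), taken from the left eigenvector of the equilibrium
projection matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import EquilibriumSolution, RateMatrixSet, StageSpace, TwoSexModel
from .mating import (
    PreferenceSpec,
    harmonic_mating_rate,
    per_capita_mating_rates,
    preference_distribution,
)
from .maternal_age import maternal_fertility
from .strategy import SexRatioStrategy

__all__ = [
    "CASE2_STAGES",
    "Case2Parameters",
    "RVRReport",
    "mating_rates_case2",
    "build_rates_case2",
    "maternal_quality_model",
    "reproductive_value_ratios",
    "trivers_willard_classification",
    "equal_investment_check",
]

#: fixed stage ordering (m01, m02, m1, m2, f01, f02, f1, f2, u11, u21, u12, u22)
CASE2_STAGES = StageSpace(
    labels=("m01", "m02", "m1", "m2", "f01", "f02", "f1", "f2", "u11", "u21", "u12", "u22"),
    roles=(
        "male-juvenile",
        "male-juvenile",
        "male-adult",
        "male-adult",
        "female-juvenile",
        "female-juvenile",
        "female-adult",
        "female-adult",
        "union",
        "union",
        "union",
        "union",
    ),
    union_partners={
        "u11": ("m1", "f1"),
        "u21": ("m2", "f1"),
        "u12": ("m1", "f2"),
        "u22": ("m2", "f2"),
    },
)


@dataclass(frozen=True)
class Case2Parameters:
    """Maternal-quality model parameters (defaults per the standard table).

    ``q`` is the probability that a mother's offspring share her quality
    (``q = q11 = q22 >= 0.5``, off-diagonals ``1 − q``).  Offspring costs
    default to ``Cm = Cf = 1`` so that fertility equals the investment rate,
    ``k_j = R_j``; all quality asymmetry then flows through ``c`` and ``R``.
    """

    R1: float = 10.0
    R2: float = 10.0
    Cm: float = 1.0
    Cf: float = 1.0
    c1: float = 0.1
    q: float = 0.65
    biased: bool = True
    d11: float = 0.1
    d21: float = 0.1
    d12: float = 0.1
    d22: float = 0.1
    mu_m01: float = 0.1
    mu_m02: float = 0.1
    mu_f01: float = 0.1
    mu_f02: float = 0.1
    mu_m1: float = 0.1
    mu_m2: float = 0.1
    mu_f1: float = 0.1
    mu_f2: float = 0.1
    alpha_m1: float = 1.0
    alpha_m2: float = 1.0
    alpha_f1: float = 1.0
    alpha_f2: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if name == "biased":
                continue
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Cm <= 0 or self.Cf <= 0:
            raise ValueError("offspring costs Cm, Cf must be > 0")
        if self.biased and not self.c1 <= 0.5:
            raise ValueError("biased male competitiveness requires c1 <= 0.5 (c2 >= c1)")
        if not 0.0 <= self.c1 <= 1.0:
            raise ValueError("c1 must lie in [0, 1]")
        if not 0.5 <= self.q <= 1.0:
            raise ValueError("quality inheritance requires 0.5 <= q <= 1")

    @property
    def c2(self) -> float:
        return 1.0 - self.c1

    def q_ij(self, i: int, j: int) -> float:
        return self.q if i == j else 1.0 - self.q

    def divorce(self, i: int, j: int) -> float:
        return getattr(self, f"d{i}{j}")

    def fertility(self, j: int, s: SexRatioStrategy) -> float:
        sj = (s.s1, s.s2)[j - 1]
        return maternal_fertility((self.R1, self.R2)[j - 1], sj, self.Cm, self.Cf)


def mating_rates_case2(params: Case2Parameters, p: np.ndarray) -> dict[str, tuple[float, float]]:
    """Per-capita mating rates {uij: (Um_ij, Uf_ij)} from the generic pipeline.

    Males choose females by abundance (random); females weigh males by the
    competitiveness factors ``(c1, c2)`` (biased).  Composed with the harmonic
    mean these reproduce the closed forms such as
    ``U_f21 = 2 c2 m2 / (c1 m1 + c2 (f + m2))``.
    """
    idx = {lab: i for i, lab in enumerate(CASE2_STAGES.labels)}
    males = np.array([p[idx["m1"]], p[idx["m2"]]])
    females = np.array([p[idx["f1"]], p[idx["f2"]]])
    female_pref = (
        PreferenceSpec("biased", weights=(params.c1, params.c2))
        if params.biased
        else PreferenceSpec("random")
    )
    male_pref = PreferenceSpec("random")
    out: dict[str, tuple[float, float]] = {}
    for i in (1, 2):
        for j in (1, 2):
            g = preference_distribution(female_pref, i - 1, males)
            h = preference_distribution(male_pref, j - 1, females)
            male_avail = males[i - 1] * h[j - 1]
            female_avail = females[j - 1] * g[i - 1]
            M = harmonic_mating_rate(male_avail, female_avail)
            out[f"u{i}{j}"] = per_capita_mating_rates(M, males[i - 1], females[j - 1])
    return out


# stage indices (m01, m02, m1, m2, f01, f02, f1, f2, u11, u21, u12, u22)
_M01, _M02, _M1, _M2, _F01, _F02, _F1, _F2, _U11, _U21, _U12, _U22 = range(12)
_UNION_IDX2 = {"u11": _U11, "u21": _U21, "u12": _U12, "u22": _U22}


def build_rates_case2(
    params: Case2Parameters, s: SexRatioStrategy, p: np.ndarray
) -> RateMatrixSet:
    """Assemble (T, B, U) for the 12-stage maternal-quality model.

    The union matrix uses the closed-form per-capita rates of the biased
    female choice composed with the harmonic mean, e.g.
    ``U_f21 = 2 c2 m2 / (c1 m1 + c2 (f + m2))``; equivalence with the generic
    mating pipeline (:func:`mating_rates_case2`) is a tested invariant.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (12,):
        raise ValueError(f"expected a 12-stage composition, got shape {p.shape}")
    n = 12

    k = {j: params.fertility(j, s) for j in (1, 2)}
    sj = {1: s.s1, 2: s.s2}

    # births split by sex (sj) and offspring quality (q_ij), by maternal quality j
    B = np.zeros((n, n))
    juv = {("m", 1): _M01, ("m", 2): _M02, ("f", 1): _F01, ("f", 2): _F02}
    for j, (cu1, cu2) in ((1, (_U11, _U21)), (2, (_U12, _U22))):
        for q_off in (1, 2):
            qs = params.q_ij(q_off, j)
            B[juv[("m", q_off)], cu1] = B[juv[("m", q_off)], cu2] = sj[j] * k[j] * qs
            B[juv[("f", q_off)], cu1] = B[juv[("f", q_off)], cu2] = (1.0 - sj[j]) * k[j] * qs

    U = np.zeros((n, n))
    c1 = params.c1 if params.biased else 0.5
    c2 = params.c2 if params.biased else 0.5
    m1_, m2_, f1_, f2_ = p[_M1], p[_M2], p[_F1], p[_F2]
    f_ = f1_ + f2_
    den1 = c1 * (f_ + m1_) + c2 * m2_  # condition-1 male pathway
    den2 = c1 * m1_ + c2 * (f_ + m2_)  # condition-2 male pathway
    um11 = 2.0 * c1 * f1_ / den1 if den1 > 0 else 0.0
    um12 = 2.0 * c1 * f2_ / den1 if den1 > 0 else 0.0
    uf1j = 2.0 * c1 * m1_ / den1 if den1 > 0 else 0.0  # Uf,1j, same for j=1,2
    um21 = 2.0 * c2 * f1_ / den2 if den2 > 0 else 0.0
    um22 = 2.0 * c2 * f2_ / den2 if den2 > 0 else 0.0
    uf2j = 2.0 * c2 * m2_ / den2 if den2 > 0 else 0.0
    U[_M1, _M1] = -(um11 + um12)
    U[_M2, _M2] = -(um21 + um22)
    U[_F1, _F1] = -(uf1j + uf2j)
    U[_F2, _F2] = -(uf1j + uf2j)
    U[_U11, _M1] = 0.5 * um11
    U[_U11, _F1] = 0.5 * uf1j
    U[_U21, _M2] = 0.5 * um21
    U[_U21, _F1] = 0.5 * uf2j
    U[_U12, _M1] = 0.5 * um12
    U[_U12, _F2] = 0.5 * uf1j
    U[_U22, _M2] = 0.5 * um22
    U[_U22, _F2] = 0.5 * uf2j

    T = np.zeros((n, n))
    # quality-specific maturation; no transitions between qualities
    for juv_i, adult_i, mu_j, alpha in (
        (_M01, _M1, params.mu_m01, params.alpha_m1),
        (_M02, _M2, params.mu_m02, params.alpha_m2),
        (_F01, _F1, params.mu_f01, params.alpha_f1),
        (_F02, _F2, params.mu_f02, params.alpha_f2),
    ):
        T[juv_i, juv_i] = -(mu_j + alpha)
        T[adult_i, juv_i] = alpha
    T[_M1, _M1] = -params.mu_m1
    T[_M2, _M2] = -params.mu_m2
    T[_F1, _F1] = -params.mu_f1
    T[_F2, _F2] = -params.mu_f2

    mu_m = (params.mu_m1, params.mu_m2)
    mu_f = (params.mu_f1, params.mu_f2)
    adult_m = (_M1, _M2)
    adult_f = (_F1, _F2)
    for i in (1, 2):
        for j in (1, 2):
            u = _UNION_IDX2[f"u{i}{j}"]
            d = params.divorce(i, j)
            T[adult_m[i - 1], u] = mu_f[j - 1] + d
            T[adult_f[j - 1], u] = mu_m[i - 1] + d
            T[u, u] = -(mu_m[i - 1] + mu_f[j - 1] + d)

    return RateMatrixSet(T=T, B=B, U=U)


def maternal_quality_model(params: Case2Parameters | None = None, **overrides) -> TwoSexModel:
    """Construct the Case-2 :class:`TwoSexModel`."""
    if params is None:
        params = Case2Parameters(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    return TwoSexModel(
        stage_space=CASE2_STAGES,
        parameters=params,
        build_rates=lambda s, p, _par=params: build_rates_case2(_par, s, p),
        name="maternal-quality two-sex model",
    )


@dataclass
class RVRReport:
    """Juvenile reproductive values by sex and quality, and their ratios.

    MRVR = v(m02)/v(m01) and FRVR = v(f02)/v(f01) measure how steeply each
    sex's reproductive value rises with quality; the ordering verdict is one
    of ``"MRVR>FRVR"``, ``"MRVR<FRVR"``, ``"MRVR=FRVR"`` at relative
    tolerance ``tol``.
    """

    v_m01: float
    v_m02: float
    v_f01: float
    v_f02: float
    MRVR: float
    FRVR: float
    verdict: str
    tol: float = 1e-3

    def summary(self) -> str:
        return (
            "Reproductive value ratios\n"
            f"  juvenile males   v(low) = {self.v_m01:.6g}, v(high) = {self.v_m02:.6g}\n"
            f"  juvenile females v(low) = {self.v_f01:.6g}, v(high) = {self.v_f02:.6g}\n"
            f"  MRVR = {self.MRVR:.6g}, FRVR = {self.FRVR:.6g}  ->  {self.verdict}"
        )


def reproductive_value_ratios(eq: EquilibriumSolution, tol: float = 1e-3) -> RVRReport:
    """Compute MRVR and FRVR from an equilibrium's left eigenvector.

    The ratios are invariant to the arbitrary scaling of reproductive values.
    A vanishing low-quality juvenile value leaves the ratio undefined.
    """
    space = eq.model.stage_space
    v = eq.v
    vals = {lab: float(v[space.index(lab)]) for lab in ("m01", "m02", "f01", "f02")}
    if abs(vals["m01"]) < 1e-14 or abs(vals["f01"]) < 1e-14:
        raise ValueError("low-quality juvenile reproductive value is zero; RVR undefined")
    mrvr = vals["m02"] / vals["m01"]
    frvr = vals["f02"] / vals["f01"]
    if abs(mrvr - frvr) <= tol * max(abs(mrvr), abs(frvr)):
        verdict = "MRVR=FRVR"
    elif mrvr > frvr:
        verdict = "MRVR>FRVR"
    else:
        verdict = "MRVR<FRVR"
    return RVRReport(
        v_m01=vals["m01"],
        v_m02=vals["m02"],
        v_f01=vals["f01"],
        v_f02=vals["f02"],
        MRVR=mrvr,
        FRVR=frvr,
        verdict=verdict,
        tol=tol,
    )


def trivers_willard_classification(ss, rvr: RVRReport) -> dict:
    """Check the SS-type ↔ RVR-ordering correspondence.

    Types 3 and 4 (high-quality mothers relatively son-biased) require
    MRVR > FRVR; Types 2 and 5 (daughter-biased) require MRVR < FRVR; a
    Type 1 interior SS requires MRVR = FRVR within tolerance.  Returns a
    verdict dict with the expected and observed orderings.
    """
    expected = {1: "MRVR=FRVR", 2: "MRVR<FRVR", 3: "MRVR>FRVR", 4: "MRVR>FRVR", 5: "MRVR<FRVR"}[
        ss.ss_type
    ]
    return {
        "ss_type": ss.ss_type,
        "expected": expected,
        "observed": rvr.verdict,
        "consistent": rvr.verdict == expected,
        "MRVR": rvr.MRVR,
        "FRVR": rvr.FRVR,
    }


def equal_investment_check(ss, eq: EquilibriumSolution, Cm: float, Cf: float) -> dict:
    """Equal-investment diagnostics at a singular strategy.

    At an interior (Type 1) SS the cost ratio equals both juvenile
    reproductive-value ratios: ``Cm/Cf = v_m01/v_f01 = v_m02/v_f02``; the
    residuals of both identities are returned.  At boundary SSs the identity
    fails in a characteristic direction and the one-sided inequalities are
    reported instead (Types 3, 4: ``Cm/Cf > v_m01/v_f01`` and
    ``< v_m02/v_f02``; Types 2, 5 reversed).
    """
    space = eq.model.stage_space
    v = eq.v
    cost_ratio = Cm / Cf
    low = float(v[space.index("m01")] / v[space.index("f01")])
    high = float(v[space.index("m02")] / v[space.index("f02")])
    out = {
        "cost_ratio": cost_ratio,
        "v_ratio_low": low,
        "v_ratio_high": high,
        "ss_type": ss.ss_type,
    }
    if ss.ss_type == 1:
        out["residual_low"] = abs(cost_ratio - low)
        out["residual_high"] = abs(cost_ratio - high)
        out["applicable"] = True
    else:
        if ss.ss_type in (3, 4):
            out["inequalities_hold"] = cost_ratio > low and cost_ratio < high
        else:
            out["inequalities_hold"] = cost_ratio < low and cost_ratio > high
        out["applicable"] = False
    return out
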