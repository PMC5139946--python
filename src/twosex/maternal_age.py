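"""Case study 1 — sex ratios that depend on maternal age.

Ten stages: male and female juveniles (m0, f0), young adults (m1, f1), old
adults (m2, f2), and the four union types uij pairing a condition-``i`` male
with a condition-``j`` female.  Unions with young females reproduce at rate
``k1`` with sex ratio ``s1``; unions with old females use ``k2`` and ``s2``.

Two offspring-cost mechanisms are supported:

* Case 1a (``beta > 0``): producing offspring raises *parental* mortality in
  unions by ``γ_j = β k_j (s_j C_m + (1−s_j) C_f)`` — the mortality cost is
  proportional to the resource value of the offspring stream.
* Case 1b (``beta = 0``, ``derive_k=True``): offspring die during the period
  of parental investment, so fertility trades off against offspring costs
  through the equal-investment relation ``k_j = R_j / (s_j C_m + (1−s_j) C_f)``.

Mating is harmonic with random (abundance-proportional) preferences on both
sides, which collapses the per-capita rates to ``U_m,ij = 2 f_j/(m+f)`` and
``U_f,ij = 2 m_i/(m+f)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import RateMatrixSet, StageSpace, TwoSexModel
from .mating import (
    PreferenceSpec,
    harmonic_mating_rate,
    per_capita_mating_rates,
    preference_distribution,
)
from .strategy import SexRatioStrategy

__all__ = [
    "CASE1_STAGES",
    "Case1Parameters",
    "offspring_costs_from_investment",
    "maternal_fertility",
    "union_mortality_increment",
    "mating_rates_case1",
    "build_rates_case1",
    "average_primary_sex_ratio",
    "fisherian_ratio",
    "maternal_age_model",
]

#: fixed stage ordering (m0, m1, m2, f0, f1, f2, u11, u21, u12, u22)
CASE1_STAGES = StageSpace(
    labels=("m0", "m1", "m2", "f0", "f1", "f2", "u11", "u21", "u12", "u22"),
    roles=(
        "male-juvenile",
        "male-adult",
        "male-adult",
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

_UNIONS = ("u11", "u21", "u12", "u22")


def offspring_costs_from_investment(
    I: float, mu_m0: float, mu_f0: float, alpha_m1: float, alpha_f1: float
) -> tuple[float, float]:
    """Average per-offspring resource costs under juvenile mortality.

    A parent invests at baseline rate ``I`` over the expected maturation
    period ``1/α`` of each offspring; offspring that die during investment
    (at juvenile mortality rate ``μ0``) waste the resources already spent, so
    the average cost per offspring rises with ``μ0``:

    ``C = I μ0 / (1 − exp(−μ0/α))``.
    """
    if min(I, mu_m0, mu_f0) <= 0 or min(alpha_m1, alpha_f1) <= 0:
        raise ValueError("investment, mortality and maturation rates must be > 0")
    Cm = I * mu_m0 / -math.expm1(-mu_m0 / alpha_m1)
    Cf = I * mu_f0 / -math.expm1(-mu_f0 / alpha_f1)
    return Cm, Cf


def maternal_fertility(Rj: float, sj: float, Cm: float, Cf: float) -> float:
    """Equal-investment fertility ``k_j = R_j / (s_j C_m + (1−s_j) C_f)``."""
    if Cm <= 0 or Cf <= 0:
        raise ValueError("offspring costs must be > 0")
    return Rj / (sj * Cm + (1.0 - sj) * Cf)


def union_mortality_increment(
    beta: float, kj: float, sj: float, Cm: float, Cf: float
) -> float:
    """Offspring-induced parental mortality ``γ_j = β k_j (s_j C_m + (1−s_j) C_f)``.

    Applied to *both* partners of any union whose female is in condition
    ``j``; zero in Case 1b (``β = 0``).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return beta * kj * (sj * Cm + (1.0 - sj) * Cf)


def fisherian_ratio(Cm: float, Cf: float) -> float:
    """Fisherian equal-investment sex ratio ``s* = C_f / (C_m + C_f)``."""
    if Cm + Cf <= 0:
        raise ValueError("Cm + Cf must be > 0")
    return Cf / (Cm + Cf)


def average_primary_sex_ratio(s: SexRatioStrategy, u_densities) -> float:
    """Union-weighted average primary sex ratio.

    ``s̄ = [s1 (u11+u21) + s2 (u12+u22)] / Σ uij`` over union densities in the
    order (u11, u21, u12, u22), normally evaluated at demographic equilibrium.
    """
    u = np.asarray(u_densities, dtype=float)
    if (u < 0).any():
        raise ValueError("union densities must be >= 0")
    total = u.sum()
    if total == 0:
        raise ValueError("average sex ratio undefined: all union densities are zero")
    return float((s.s1 * (u[0] + u[1]) + s.s2 * (u[2] + u[3])) / total)


@dataclass(frozen=True)
class Case1Parameters:
    """Maternal-age model parameters (defaults per the standard table).

    ``derive_k=False`` takes ``k1, k2`` as fixed reproductive rates (Case 1a);
    ``derive_k=True`` derives them from resource investment rates ``R1, R2``
    and the offspring costs via the equal-investment relation (Case 1b).
    Costs ``Cm, Cf`` are given directly (as in the published scenarios);
    :func:`offspring_costs_from_investment` offers the derivation from a
    baseline investment rate ``I`` as an optional path.
    """

    k1: float = 10.0
    k2: float = 10.0
    R1: float = 10.0
    R2: float = 10.0
    Cm: float = 0.4
    Cf: float = 0.6
    I: float = 1.0
    beta: float = 0.2
    derive_k: bool = False
    d11: float = 0.1
    d21: float = 0.1
    d12: float = 0.1
    d22: float = 0.1
    mu_m0: float = 0.1
    mu_m1: float = 0.1
    mu_m2: float = 0.1
    mu_f0: float = 0.1
    mu_f1: float = 0.1
    mu_f2: float = 0.1
    alpha_m1: float = 0.5
    alpha_m2: float = 0.5
    alpha_f1: float = 0.5
    alpha_f2: float = 0.5

    def __post_init__(self) -> None:
        rates = {
            f.name: getattr(self, f.name)
            for f in self.__dataclass_fields__.values()
            if f.name not in ("derive_k",)
        }
        for name, val in rates.items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        if self.Cm <= 0 or self.Cf <= 0:
            raise ValueError("offspring costs Cm, Cf must be > 0")

    def divorce(self, i: int, j: int) -> float:
        return getattr(self, f"d{i}{j}")

    def fertility(self, j: int, s: SexRatioStrategy) -> float:
        sj = (s.s1, s.s2)[j - 1]
        if self.derive_k:
            Rj = (self.R1, self.R2)[j - 1]
            return maternal_fertility(Rj, sj, self.Cm, self.Cf)
        return (self.k1, self.k2)[j - 1]

    def gamma(self, j: int, s: SexRatioStrategy) -> float:
        sj = (s.s1, s.s2)[j - 1]
        return union_mortality_increment(self.beta, self.fertility(j, s), sj, self.Cm, self.Cf)


def mating_rates_case1(p: np.ndarray) -> dict[str, tuple[float, float]]:
    """Per-capita mating rates {uij: (Um_ij, Uf_ij)} from the generic pipeline.

    Random preferences on both sides composed with the harmonic mean; with
    every pool positive these equal the closed forms ``2 f_j/(m+f)`` and
    ``2 m_i/(m+f)``.
    """
    idx = {lab: i for i, lab in enumerate(CASE1_STAGES.labels)}
    males = np.array([p[idx["m1"]], p[idx["m2"]]])
    females = np.array([p[idx["f1"]], p[idx["f2"]]])
    pref = PreferenceSpec("random")
    out: dict[str, tuple[float, float]] = {}
    for i in (1, 2):
        for j in (1, 2):
            g = preference_distribution(pref, i - 1, males)  # female j's choice over males
            h = preference_distribution(pref, j - 1, females)  # male i's choice over females
            male_avail = males[i - 1] * h[j - 1]
            female_avail = females[j - 1] * g[i - 1]
            M = harmonic_mating_rate(male_avail, female_avail)
            out[f"u{i}{j}"] = per_capita_mating_rates(M, males[i - 1], females[j - 1])
    return out


# stage indices (m0, m1, m2, f0, f1, f2, u11, u21, u12, u22)
_M0, _M1, _M2, _F0, _F1, _F2, _U11, _U21, _U12, _U22 = range(10)
_UNION_IDX = {"u11": _U11, "u21": _U21, "u12": _U12, "u22": _U22}


def build_rates_case1(
    params: Case1Parameters, s: SexRatioStrategy, p: np.ndarray
) -> RateMatrixSet:
    """Assemble (T, B, U) for the 10-stage maternal-age model.

    The union matrix uses the closed-form per-capita rates of the
    random-preference harmonic mean, ``U_m,ij = 2 f_j/(m+f)`` and
    ``U_f,ij = 2 m_i/(m+f)``; their equivalence with the generic
    preference→availability→mean→per-capita pipeline
    (:func:`mating_rates_case1`) is a tested invariant.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (10,):
        raise ValueError(f"expected a 10-stage composition, got shape {p.shape}")
    n = 10

    k1 = params.fertility(1, s)
    k2 = params.fertility(2, s)
    g1 = params.gamma(1, s)
    g2 = params.gamma(2, s)

    # births: union uij delivers male juveniles at sj*kj, females at (1-sj)*kj
    B = np.zeros((n, n))
    B[_M0, _U11] = B[_M0, _U21] = s.s1 * k1
    B[_M0, _U12] = B[_M0, _U22] = s.s2 * k2
    B[_F0, _U11] = B[_F0, _U21] = (1.0 - s.s1) * k1
    B[_F0, _U12] = B[_F0, _U22] = (1.0 - s.s2) * k2

    # union formation: per-capita losses on singles, half-gains into unions
    U = np.zeros((n, n))
    tot = p[_M1] + p[_M2] + p[_F1] + p[_F2]
    if tot > 0.0:
        um1 = 2.0 * p[_F1] / tot  # Um,i1: rate of males i acquiring young females
        um2 = 2.0 * p[_F2] / tot
        uf1 = 2.0 * p[_M1] / tot  # Uf,1j: rate of females j acquiring young males
        uf2 = 2.0 * p[_M2] / tot
        U[_M1, _M1] = U[_M2, _M2] = -(um1 + um2)
        U[_F1, _F1] = U[_F2, _F2] = -(uf1 + uf2)
        U[_U11, _M1] = 0.5 * um1
        U[_U11, _F1] = 0.5 * uf1
        U[_U21, _M2] = 0.5 * um1
        U[_U21, _F1] = 0.5 * uf2
        U[_U12, _M1] = 0.5 * um2
        U[_U12, _F2] = 0.5 * uf1
        U[_U22, _M2] = 0.5 * um2
        U[_U22, _F2] = 0.5 * uf2

    # transitions: maturation chains, union aging, divorce and death returns
    T = np.zeros((n, n))
    T[_M0, _M0] = -(params.mu_m0 + params.alpha_m1)
    T[_M1, _M0] = params.alpha_m1
    T[_M1, _M1] = -(params.mu_m1 + params.alpha_m2)
    T[_M2, _M1] = params.alpha_m2
    T[_M2, _M2] = -params.mu_m2
    T[_F0, _F0] = -(params.mu_f0 + params.alpha_f1)
    T[_F1, _F0] = params.alpha_f1
    T[_F1, _F1] = -(params.mu_f1 + params.alpha_f2)
    T[_F2, _F1] = params.alpha_f2
    T[_F2, _F2] = -params.mu_f2

    mu_m = (params.mu_m1, params.mu_m2)
    mu_f = (params.mu_f1, params.mu_f2)
    gam = (g1, g2)
    for i in (1, 2):
        for j in (1, 2):
            u = _UNION_IDX[f"u{i}{j}"]
            d = params.divorce(i, j)
            g = gam[j - 1]
            # partner death (mortality inflated by γ) or divorce frees a single
            T[(_M1, _M2)[i - 1], u] = mu_f[j - 1] + g + d
            T[(_F1, _F2)[j - 1], u] = mu_m[i - 1] + g + d
            out = mu_m[i - 1] + mu_f[j - 1] + 2.0 * g + d
            # union-type transitions at partner maturation (young -> old only)
            if i == 1:
                T[_UNION_IDX[f"u2{j}"], u] += params.alpha_m2
                out += params.alpha_m2
            if j == 1:
                T[_UNION_IDX[f"u{i}2"], u] += params.alpha_f2
                out += params.alpha_f2
            T[u, u] = -out

    return RateMatrixSet(T=T, B=B, U=U)


def maternal_age_model(params: Case1Parameters | None = None, **overrides) -> TwoSexModel:
    """Construct the Case-1 :class:`TwoSexModel` (Case 1a by default).

    Keyword overrides are applied on top of the defaults, e.g.
    ``maternal_age_model(k1=5, k2=15)``.
    """
    if params is None:
        params = Case1Parameters(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    return TwoSexModel(
        stage_space=CASE1_STAGES,
        parameters=params,
        build_rates=lambda s, p, _par=params: build_rates_case1(_par, s, p),
        name="maternal-age two-sex model"
        + (" (offspring-mortality cost)" if params.derive_k else " (parental-mortality cost)"),
    )
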