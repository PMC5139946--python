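"""Mating preferences and generalized-mean mating functions.

Union formation in a two-sex model is driven by a total mating function
``M_ij`` giving the rate at which condition-``i`` males and condition-``j``
females form new unions.  ``M_ij`` acts on *availabilities* — the densities of
single adults of each sex weighted by the partner's preference for them — and
is built here from the Hölder (generalized weighted mean) family, of which the
classic harmonic-mean marriage function is the ``a = -1, b = 1/2`` member.

Availabilities are computed only over single adult stages: juveniles and
individuals already in unions never enter the mating market.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PreferenceSpec",
    "MatingFunctionSpec",
    "preference_distribution",
    "holder_mating_rate",
    "harmonic_mating_rate",
    "per_capita_mating_rates",
]


@dataclass(frozen=True)
class PreferenceSpec:
    """A mating-preference rule over partner conditions.

    kind
        ``"assortative"`` — only partners of one's own condition;
        ``"random"`` — partners in proportion to their abundance;
        ``"biased"`` — abundances weighted by per-condition attractiveness
        (competitiveness) factors ``weights``.
    weights
        Attractiveness factors ``c_i`` (``biased`` only).  A partner condition
        with ``c_i = 0`` is never chosen; equal weights reduce to ``random``.
    """

    kind: str = "random"
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("assortative", "random", "biased"):
            raise ValueError(f"unknown preference kind {self.kind!r}")
        if self.kind == "biased":
            if self.weights is None:
                raise ValueError("biased preference requires weights")
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any():
                raise ValueError("attractiveness factors must be >= 0")
            object.__setattr__(self, "weights", tuple(float(x) for x in w))


@dataclass(frozen=True)
class MatingFunctionSpec:
    """Hölder-mean mating function with exponent ``a < 0`` and weight ``b``.

    The harmonic special case is ``a = -1, b = 1/2``.
    """

    a: float = -1.0
    b: float = 0.5

    def __post_init__(self) -> None:
        if not self.a < 0:
            raise ValueError("Hölder exponent a must be < 0")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("weight b must lie in [0, 1]")


def preference_distribution(
    spec: PreferenceSpec, own_condition: int, partner_densities: np.ndarray
) -> np.ndarray:
    """Probability distribution over partner conditions.

    Returns the preference distribution (g_j(i) for females choosing among
    male conditions, or h_i(j) for males choosing among female conditions)
    evaluated on the given partner-pool densities.  The result sums to 1 for
    any nondegenerate pool; an all-zero (weighted) pool returns the zero
    vector, meaning no mating.
    """
    dens = np.asarray(partner_densities, dtype=float)
    if (dens < 0).any():
        raise ValueError("partner densities must be >= 0")
    n = dens.size
    if spec.kind == "assortative":
        out = np.zeros(n)
        out[own_condition] = 1.0
        return out
    if spec.kind == "random":
        weighted = dens
    else:  # biased
        w = np.asarray(spec.weights, dtype=float)
        if w.size != n:
            raise ValueError("weights and partner pool size mismatch")
        weighted = w * dens
    total = weighted.sum()
    if total == 0.0:
        return np.zeros(n)
    return weighted / total


def holder_mating_rate(
    spec: MatingFunctionSpec, male_avail: float, female_avail: float
) -> float:
    """Generalized weighted mean of the two sex-specific availabilities.

    ``M = (b * female_avail**a + (1-b) * male_avail**a)**(1/a)`` with ``a < 0``;
    zero whenever either availability is zero (no partners of one sex means no
    unions, the defining two-sex axiom).
    """
    x, y = float(male_avail), float(female_avail)
    if x < 0 or y < 0:
        raise ValueError("availabilities must be >= 0")
    if x == 0.0 or y == 0.0:
        return 0.0
    a, b = spec.a, spec.b
    return float((b * y**a + (1.0 - b) * x**a) ** (1.0 / a))


def harmonic_mating_rate(male_avail: float, female_avail: float) -> float:
    """Harmonic-mean mating function ``2xy / (x + y)``; 0 when ``x + y = 0``."""
    x, y = float(male_avail), float(female_avail)
    if x < 0 or y < 0:
        raise ValueError("availabilities must be >= 0")
    s = x + y
    if s == 0.0:
        return 0.0
    return 2.0 * x * y / s


def per_capita_mating_rates(Mij: float, mi: float, fj: float) -> tuple[float, float]:
    """Per-capita male and female mating rates ``(M/mi, M/fj)``.

    Defined as 0 when the respective single-adult density is 0 (an extinct
    partner pool forms no unions).
    """
    um = Mij / mi if mi > 0 else 0.0
    uf = Mij / fj if fj > 0 else 0.0
    return um, uf
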