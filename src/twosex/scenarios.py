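"""Seeded random scenario generation for property testing.

Draws parameter sets that are always valid for their case: rate-type
parameters log-uniform on [0.05, 2] (a realistic spread around the default
order of magnitude of 0.1–1 per unit time), probability-type parameters
uniform on their constraint sets (the sex-ratio box minus its inviable
corners, competitiveness ``c1 < 0.5`` with ``c2 = 1 − c1``, inheritance
``q ∈ [0.5, 1)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TwoSexModel
from .maternal_age import Case1Parameters, maternal_age_model
from .maternal_quality import Case2Parameters, maternal_quality_model
from .strategy import SexRatioStrategy

__all__ = ["ScenarioDraw", "generate_scenario", "CASES"]

CASES = ("case1a", "case1b", "case2")

RATE_LOW, RATE_HIGH = 0.05, 2.0
#: margin keeping random strategies away from the inviable corners
_S_MARGIN = 0.02


def _log_uniform(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    return np.exp(rng.uniform(np.log(RATE_LOW), np.log(RATE_HIGH), n))


@dataclass(frozen=True)
class ScenarioDraw:
    """A reproducible random scenario: case label, parameters, strategy."""

    case: str
    seed: int
    parameters: object
    strategy: SexRatioStrategy

    def model(self) -> TwoSexModel:
        if self.case in ("case1a", "case1b"):
            return maternal_age_model(self.parameters)
        return maternal_quality_model(self.parameters)


def generate_scenario(case: str, seed: int, require_viable: bool = False) -> ScenarioDraw:
    """Draw a valid random scenario for the given case, fixed by ``seed``.

    With ``require_viable`` the draw is rejection-sampled (from the same
    seeded stream, so still reproducible) until the resident equilibrium at
    the drawn strategy sustains both sexes — random rate combinations can
    otherwise collapse onto a single-sex state where sex-ratio evolution is
    vacuous.
    """
    if case not in CASES:
        raise ValueError(f"case must be one of {CASES}")
    rng = np.random.default_rng(seed)
    for _ in range(60):
        draw = _draw_once(case, seed, rng)
        if not require_viable:
            return draw
        from .core import ConvergenceError, solve_equilibrium

        try:
            eq = solve_equilibrium(draw.model(), draw.strategy)
        except ConvergenceError:
            continue
        space = draw.model().stage_space
        p = eq.p_hat.values
        males = sum(p[i] for i in space.indices("male-adult"))
        females = sum(p[i] for i in space.indices("female-adult"))
        if min(males, females) > 1e-6:
            return draw
    raise RuntimeError(f"no viable {case} scenario found from seed {seed}")


def _draw_once(case: str, seed: int, rng: np.random.Generator) -> ScenarioDraw:
    s = SexRatioStrategy(*rng.uniform(_S_MARGIN, 1.0 - _S_MARGIN, 2))

    if case in ("case1a", "case1b"):
        r = _log_uniform(rng, 16)
        params = Case1Parameters(
            k1=float(r[0] * 5),  # fertilities span a higher range than losses
            k2=float(r[1] * 5),
            R1=float(r[2] * 5),
            R2=float(r[3] * 5),
            Cm=float(r[4]),
            Cf=float(r[5]),
            beta=0.0 if case == "case1b" else float(r[6] * 0.25),
            derive_k=case == "case1b",
            d11=float(r[7]),
            d21=float(r[7]),
            d12=float(r[7]),
            d22=float(r[7]),
            mu_m0=float(r[8]),
            mu_m1=float(r[9]),
            mu_m2=float(r[10]),
            mu_f0=float(r[11]),
            mu_f1=float(r[12]),
            mu_f2=float(r[13]),
            alpha_m1=float(r[14]),
            alpha_m2=float(r[15]),
            alpha_f1=float(r[14]),
            alpha_f2=float(r[15]),
        )
    else:
        r = _log_uniform(rng, 12)
        params = Case2Parameters(
            R1=float(r[0] * 5),
            R2=float(r[1] * 5),
            Cm=1.0,
            Cf=1.0,
            c1=float(rng.uniform(0.05, 0.5)),
            q=float(rng.uniform(0.5, 0.98)),
            d11=float(r[2]),
            d21=float(r[2]),
            d12=float(r[2]),
            d22=float(r[2]),
            mu_m01=float(r[3]),
            mu_m02=float(r[4]),
            mu_f01=float(r[5]),
            mu_f02=float(r[6]),
            mu_m1=float(r[7]),
            mu_m2=float(r[8]),
            mu_f1=float(r[9]),
            mu_f2=float(r[10]),
            alpha_m1=float(r[11]),
            alpha_m2=float(r[11]),
            alpha_f1=float(r[11]),
            alpha_f2=float(r[11]),
        )
    return ScenarioDraw(case=case, seed=seed, parameters=params, strategy=s)
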