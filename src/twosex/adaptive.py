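"""Multidimensional adaptive dynamics of the bivariate sex-ratio trait.

A monomorphic resident with strategy ``s`` sets the demographic environment
(its equilibrium stage frequencies ``p̂``).  A rare mutant with strategy
``s′`` experiences that environment; its growth rate ``λ′`` is the dominant
eigenvalue of a mutant projection matrix evaluated at ``p̂``, and the invasion
fitness is ``Λ_s(s′) = λ′(p̂) − λ``.  The selection gradient
``D(s) = ∂λ′/∂s′ᵀ|_{s′=s}`` drives the canonical equation

    ds/dt = V(s) Dᵀ(s),   V(s) = diag(s1(1−s1), s2(1−s2)),

whose mutational variance matrix vanishes on the boundary of the constraint
box so trajectories never leave [0,1]².  Stationary points are singular
strategies (SSs): one interior type where ``D = 0`` and four boundary types
where the free component's gradient vanishes while the fixed component's
gradient points out of the box.

Mutant bookkeeping
------------------
``literal`` mode (the default and reference construction) builds the mutant
matrix as the resident structure with ``s′`` substituted wherever the sex
ratio appears and the stage frequencies frozen at the resident ``p̂``: the
mutant is structurally identical to the resident but plays its own strategy
in the resident's environment.  Self-invasion is then trivially neutral.

``expanded`` mode instead books the mutant lineage genetically.  Mutants are
dominant: any offspring with a mutant parent shows the mutant phenotype.
The mutant subpopulation has its own copies of every single stage plus *two*
copies of every union type — one with a mutant male and a resident female
(births use the resident female's sex ratio) and one with a resident male
and a mutant female (births use ``s′``).  Exact self-invasion neutrality
pins the credit factors: a mutant single's mating creates one mutant-side
union (full rate), dissolution returns the mutant partner at the full rate,
and each mixed union's births are credited to the mutant lineage at half the
union fertility — a rare dominant allele is carried by half the offspring of
a heterozygote × wild-type pair.  With these factors the resident
eigen-system lifts exactly onto the mutant block and ``Λ_s(s) = 0`` to
machine precision.

The two modes share the self-invasion property but weight the male and
female transmission pathways differently, so their selection gradients — and
in delicately balanced scenarios their singular strategies — can differ; the
methods note discusses the choice of default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import (
    EquilibriumSolution,
    TwoSexModel,
    TwoSexModelError,
    dominant_eigen_triple,
    solve_equilibrium,
)
from .strategy import SexRatioStrategy

__all__ = [
    "MutantModel",
    "SelectionGradientResult",
    "SingularStrategyReport",
    "TrajectoryResult",
    "NeutralLineReport",
    "build_mutant_model",
    "invasion_fitness",
    "selection_gradient",
    "mutational_variance",
    "canonical_rhs",
    "integrate_strategy_trajectory",
    "find_singular_strategy",
    "detect_neutral_line",
    "union_weighted_sex_ratio",
]

_MODES = ("expanded", "literal")
#: default differentiation step for selection gradients
GRAD_STEP = 1e-6


def mutational_variance(s: SexRatioStrategy) -> np.ndarray:
    """Mutational variance matrix ``V(s) = diag(s1(1−s1), s2(1−s2))``.

    Diagonal (no pleiotropy) and vanishing on the constraint boundary, which
    confines the canonical flow to the box [0,1]².
    """
    return np.diag([s.s1 * (1.0 - s.s1), s.s2 * (1.0 - s.s2)])


def canonical_rhs(s: SexRatioStrategy, D: np.ndarray) -> np.ndarray:
    """Canonical-equation right-hand side ``V(s) Dᵀ``."""
    return mutational_variance(s) @ np.asarray(D, dtype=float)


class MutantModel:
    """Mutant projection-matrix factory for a fixed resident environment.

    Precomputes everything that depends only on the resident (strategy,
    equilibrium frequencies, stage bookkeeping) so that ``matrix(s_prime)``
    is cheap to evaluate repeatedly, e.g. inside finite differences.
    """

    def __init__(
        self,
        model: TwoSexModel,
        resident: SexRatioStrategy,
        resident_eq: EquilibriumSolution,
        mode: str = "literal",
        residual_tol: float = 1e-8,
        birth_credit: float = 0.5,
    ):
        self.birth_credit = birth_credit
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if resident_eq.residual > residual_tol:
            raise TwoSexModelError(
                f"resident equilibrium residual {resident_eq.residual:.2e} "
                f"exceeds {residual_tol:.0e}; refuse to build mutant"
            )
        self.model = model
        self.resident = resident
        self.p_hat = resident_eq.p_hat.values
        self.lam_resident = resident_eq.lam
        self.mode = mode
        space = model.stage_space
        self._singles = [i for i, r in enumerate(space.roles) if r != "union"]
        self._unions = [space.labels[i] for i in space.indices("union")]
        self._res_rates = model.build_rates(resident, self.p_hat)
        if mode == "expanded":
            # mutant layout: resident single stages, then (u_m, u_f) per union
            self._labels = [space.labels[i] for i in self._singles]
            for u in self._unions:
                self._labels += [u + "_m", u + "_f"]
            self._pos = {lab: i for i, lab in enumerate(self._labels)}

    @property
    def n_stages(self) -> int:
        return len(self._labels) if self.mode == "expanded" else self.model.stage_space.n

    @property
    def stage_labels(self) -> list[str]:
        if self.mode == "expanded":
            return list(self._labels)
        return list(self.model.stage_space.labels)

    def matrix(self, s_prime: SexRatioStrategy) -> np.ndarray:
        """The mutant projection matrix ``A′(s′)`` at the resident ``p̂``."""
        if self.mode == "literal":
            return self.model.projection(s_prime, self.p_hat)
        return self._expanded_matrix(s_prime)

    def _expanded_matrix(self, s_prime: SexRatioStrategy) -> np.ndarray:
        space = self.model.stage_space
        res = self._res_rates
        mut = self.model.build_rates(s_prime, self.p_hat)
        singles = self._singles
        pos = self._pos
        n = len(self._labels)
        T = np.zeros((n, n))
        B = np.zeros((n, n))
        U = np.zeros((n, n))

        # single-stage block: maturation/mortality and mating losses are
        # strategy independent, shared with the resident
        for a, ia in enumerate(singles):
            la = space.labels[ia]
            for b, ib in enumerate(singles):
                lb = space.labels[ib]
                T[pos[la], pos[lb]] = res.T[ia, ib]
            U[pos[la], pos[la]] = res.U[ia, ia]

        for u in self._unions:
            iu = space.index(u)
            mstage, fstage = space.union_partners[u]
            im, if_ = space.index(mstage), space.index(fstage)
            # union formation: full credit — one mutant single's mating makes
            # one mutant-side union (the resident half-gains are ½Um, ½Uf)
            U[pos[u + "_m"], pos[mstage]] += 2.0 * res.U[iu, im]
            U[pos[u + "_f"], pos[fstage]] += 2.0 * res.U[iu, if_]
            for side, src in (("_m", res), ("_f", mut)):
                cu = pos[u + side]
                # union column of T: diagonal, same-side union transitions,
                # and the return of the *mutant* partner only
                T[cu, cu] = src.T[iu, iu]
                for u2 in self._unions:
                    iu2 = space.index(u2)
                    if u2 != u and src.T[iu2, iu] != 0.0:
                        T[pos[u2 + side], cu] = src.T[iu2, iu]
                own = mstage if side == "_m" else fstage
                iown = space.index(own)
                T[pos[own], cu] = src.T[iown, iu]
                # births: half credit, resident sex ratio in mutant-male
                # unions (res), mutant sex ratio in mutant-female unions (mut)
                for a, ia in enumerate(singles):
                    if src.B[ia, iu] != 0.0:
                        B[pos[space.labels[ia]], cu] = self.birth_credit * src.B[ia, iu]
        return (T + B + U) / 3.0

    def growth_rate(self, s_prime: SexRatioStrategy) -> float:
        """Dominant eigenvalue ``λ′`` of the mutant matrix."""
        vals = np.linalg.eigvals(self.matrix(s_prime))
        k = int(np.argmax(vals.real))
        lam = vals[k]
        if abs(lam.imag) > 1e-9:
            raise TwoSexModelError(
                f"mutant dominant eigenvalue has imaginary part {lam.imag:.3e}"
            )
        return float(lam.real)


def build_mutant_model(
    model: TwoSexModel,
    resident: SexRatioStrategy,
    resident_eq: EquilibriumSolution,
    s_prime: SexRatioStrategy,
    mode: str = "literal",
) -> np.ndarray:
    """The mutant projection matrix ``A′`` for strategy ``s′``."""
    return MutantModel(model, resident, resident_eq, mode).matrix(s_prime)


def invasion_fitness(
    model: TwoSexModel,
    resident: SexRatioStrategy,
    resident_eq: EquilibriumSolution,
    s_prime: SexRatioStrategy,
    mode: str = "literal",
) -> float:
    """Invasion fitness ``Λ_s(s′) = λ′(p̂) − λ``."""
    mm = MutantModel(model, resident, resident_eq, mode)
    return mm.growth_rate(s_prime) - resident_eq.lam


@dataclass
class SelectionGradientResult:
    """Selection gradient ``D(s)`` with the method and step that produced it."""

    D: np.ndarray
    method: str
    step: float
    lam: float
    strategy: SexRatioStrategy

    def __iter__(self):
        yield from self.D


def _fd_points(x: float, h: float) -> tuple[list[float], list[float]]:
    """Stencil abscissae/weights for d/dx at x within [0,1] (order 2)."""
    if x - h >= 0.0 and x + h <= 1.0:
        return [x - h, x + h], [-0.5 / h, 0.5 / h]
    if x + 2 * h <= 1.0:  # forward one-sided
        return [x, x + h, x + 2 * h], [-1.5 / h, 2.0 / h, -0.5 / h]
    # backward one-sided
    return [x, x - h, x - 2 * h], [1.5 / h, -2.0 / h, 0.5 / h]


def selection_gradient(
    model: TwoSexModel,
    resident: SexRatioStrategy,
    resident_eq: EquilibriumSolution,
    mode: str = "literal",
    method: str = "finite-difference",
    step: float = GRAD_STEP,
) -> SelectionGradientResult:
    """Both components of ``∂λ′/∂s′`` at ``s′ = s``.

    ``finite-difference`` differentiates the mutant growth rate directly
    (central, falling back to second-order one-sided at the box boundary).
    ``vec-formula`` contracts the eigenvalue-sensitivity identity
    ``D = (w′ᵀ ⊗ v′ᵀ) dvecA′/ds′ᵀ`` with ``v′ᵀw′ = 1``, using the same
    stencil for the matrix derivative.  The two agree to first order and are
    cross-checked in the test-suite at 1e-4 relative.
    """
    mm = MutantModel(model, resident, resident_eq, mode)
    s = resident.as_array()
    D = np.empty(2)
    if method in ("finite-difference", "fd"):
        for k in range(2):
            xs, ws = _fd_points(s[k], step)
            acc = 0.0
            for x, wgt in zip(xs, ws):
                sp = s.copy()
                sp[k] = x
                acc += wgt * mm.growth_rate(SexRatioStrategy(sp[0], sp[1]))
            D[k] = acc
        label = "finite-difference"
    elif method in ("vec-formula", "vec"):
        A0 = mm.matrix(resident)
        lam, w, v = dominant_eigen_triple(A0)
        for k in range(2):
            xs, ws = _fd_points(s[k], step)
            dA = np.zeros_like(A0)
            for x, wgt in zip(xs, ws):
                sp = s.copy()
                sp[k] = x
                dA += wgt * mm.matrix(SexRatioStrategy(sp[0], sp[1]))
            D[k] = v @ dA @ w
        label = "vec-formula"
    else:
        raise ValueError(f"unknown gradient method {method!r}")
    return SelectionGradientResult(
        D=D, method=label, step=step, lam=resident_eq.lam, strategy=resident
    )


class _GradientField:
    """Selection-gradient evaluator with warm-started resident equilibria."""

    def __init__(
        self,
        model: TwoSexModel,
        mode: str = "literal",
        method: str = "finite-difference",
        eq_tol: float = 1e-10,
    ):
        self.model = model
        self.mode = mode
        self.method = method
        self.eq_tol = eq_tol
        self._warm: np.ndarray | None = None
        self.n_evals = 0

    def equilibrium(self, s: SexRatioStrategy) -> EquilibriumSolution:
        eq = solve_equilibrium(self.model, s, p0=self._warm, tol=self.eq_tol)
        if self._warm is not None and self._is_single_sex(eq):
            # single-sex states absorb the flow for *any* strategy, so a
            # poisoned warm start can stick there; retry from uniform
            eq_cold = solve_equilibrium(self.model, s, p0=None, tol=self.eq_tol)
            if not self._is_single_sex(eq_cold):
                eq = eq_cold
        self._warm = eq.p_hat.values
        return eq

    def _is_single_sex(self, eq: EquilibriumSolution) -> bool:
        return equilibrium_is_single_sex(self.model, eq)

    def __call__(self, s: SexRatioStrategy) -> tuple[np.ndarray, EquilibriumSolution]:
        eq = self.equilibrium(s)
        res = selection_gradient(self.model, s, eq, mode=self.mode, method=self.method)
        self.n_evals += 1
        return res.D, eq


def equilibrium_is_single_sex(
    model: TwoSexModel, eq: EquilibriumSolution, tol: float = 1e-6
) -> bool:
    """True when one sex has effectively vanished at equilibrium.

    On such degenerate states the sex-ratio strategy has no demographic
    effect, the selection gradient is identically zero, and singular-strategy
    classification is meaningless.
    """
    space = model.stage_space
    p = eq.p_hat.values
    males = sum(p[i] for i in space.indices("male-adult"))
    females = sum(p[i] for i in space.indices("female-adult"))
    return bool(min(males, females) < tol)


def union_weighted_sex_ratio(
    model: TwoSexModel,
    s: SexRatioStrategy,
    eq: EquilibriumSolution,
    fertility_weighted: bool = False,
) -> float:
    """Average primary sex ratio ``s̄`` at equilibrium.

    Each union contributes its female partner's sex ratio, weighted by the
    union stage's equilibrium frequency.  With ``fertility_weighted`` the
    weights additionally carry the union's reproductive rate ``k_j``, giving
    the male fraction among *births*; the two coincide when all union types
    share one fertility.  On a selectively neutral line with unequal
    fertilities it is the fertility-weighted average that is shared by all
    endpoints.
    """
    space = model.stage_space
    female_adults = space.indices("female-adult")
    num = 0.0
    den = 0.0
    for iu in space.indices("union"):
        _, fstage = space.union_partners[space.labels[iu]]
        cond = female_adults.index(space.index(fstage))  # 0-based condition
        sj = (s.s1, s.s2)[cond]
        wu = eq.p_hat.values[iu]
        if fertility_weighted:
            wu *= model.parameters.fertility(cond + 1, s)
        num += sj * wu
        den += wu
    if den == 0:
        raise ValueError("no unions at equilibrium; average sex ratio undefined")
    return num / den


@dataclass
class TrajectoryResult:
    """A canonical-equation trajectory through (s1, s2) trait space."""

    times: np.ndarray
    strategies: np.ndarray  # shape (n, 2)
    endpoint: SexRatioStrategy
    gradient_at_end: np.ndarray
    rhs_at_end: np.ndarray
    converged: bool
    s_bar_at_end: float
    lam_at_end: float
    n_gradient_evals: int

    def summary(self) -> str:
        return (
            f"Canonical-equation trajectory: {len(self.times)} points, "
            f"t_final = {self.times[-1]:.4g}\n"
            f"  endpoint s = ({self.endpoint.s1:.6f}, {self.endpoint.s2:.6f}), "
            f"s_bar = {self.s_bar_at_end:.6f}\n"
            f"  |D|_inf = {np.max(np.abs(self.gradient_at_end)):.3e}, "
            f"|ds/dt|_inf = {np.max(np.abs(self.rhs_at_end)):.3e}, "
            f"converged = {self.converged}"
        )


def integrate_strategy_trajectory(
    model: TwoSexModel,
    s0: SexRatioStrategy,
    mode: str = "literal",
    stop_tol: float = 1e-7,
    gradient_tol: float = 1e-6,
    t_max: float = 5e4,
    max_chunks: int = 400,
    method: str = "finite-difference",
) -> TrajectoryResult:
    """Integrate ``ds/dt = V(s) Dᵀ(s)`` from an interior start.

    The resident equilibrium is re-solved (warm-started from the previous
    ``p̂``) at every gradient evaluation.  Integration proceeds in adaptive
    time chunks and stops when ``|ds/dt|_∞ < stop_tol`` *or*
    ``|D|_∞ < gradient_tol`` (the latter catches arrival on a selectively
    neutral line, where the mutational variance stays finite), or at
    ``t_max``.  Round-off excursions outside [0,1]² are clamped; the variance
    factor already vanishes on the boundary.
    """
    if not (0.0 < s0.s1 < 1.0 and 0.0 < s0.s2 < 1.0):
        raise ValueError("trajectory start must be strictly interior")
    gf = _GradientField(model, mode=mode, method=method)

    def rhs(_t, y):
        s = SexRatioStrategy(float(np.clip(y[0], 0, 1)), float(np.clip(y[1], 0, 1)))
        D, _ = gf(s)
        return canonical_rhs(s, D)

    from scipy.integrate import solve_ivp

    y = s0.as_array()
    t = 0.0
    chunk = 5.0
    times = [0.0]
    path = [y.copy()]
    converged = False
    for _ in range(max_chunks):
        s_cur = SexRatioStrategy(float(np.clip(y[0], 0, 1)), float(np.clip(y[1], 0, 1)))
        D, eq = gf(s_cur)
        dsdt = canonical_rhs(s_cur, D)
        if np.max(np.abs(dsdt)) < stop_tol or np.max(np.abs(D)) < gradient_tol:
            converged = True
            break
        if t >= t_max:
            break
        sol = solve_ivp(
            rhs, (t, min(t + chunk, t_max)), y, method="RK23", rtol=1e-6, atol=1e-9
        )
        if not sol.success:
            raise TwoSexModelError(f"canonical-equation integration failed: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, 1.0)
        t = sol.t[-1]
        times.extend(sol.t[1:].tolist())
        path.extend(np.clip(sol.y[:, 1:].T, 0.0, 1.0).tolist())
        # grow chunks as the flow slows down
        chunk = min(chunk * 1.6, 2000.0)

    s_end = SexRatioStrategy(float(np.clip(y[0], 0, 1)), float(np.clip(y[1], 0, 1)))
    D_end, eq_end = gf(s_end)
    return TrajectoryResult(
        times=np.asarray(times),
        strategies=np.asarray(path),
        endpoint=s_end,
        gradient_at_end=D_end,
        rhs_at_end=canonical_rhs(s_end, D_end),
        converged=converged,
        s_bar_at_end=union_weighted_sex_ratio(model, s_end, eq_end),
        lam_at_end=eq_end.lam,
        n_gradient_evals=gf.n_evals,
    )


@dataclass
class SingularStrategyReport:
    """A located singular strategy and its classification.

    ``ss_type`` follows the five-type scheme: 1 interior (both gradient
    components zero); 2–5 boundary (s2=0, s2=1, s1=0, s1=1 respectively, with
    the free component's gradient zero and the fixed component's gradient
    pointing out of the box).  ``neutral_line`` flags degeneracy detected by
    trajectory multi-starts (see :func:`detect_neutral_line`).
    """

    location: SexRatioStrategy | None
    ss_type: int | None
    gradient_at_ss: np.ndarray | None
    candidates: list = field(default_factory=list)
    neutral_line: bool | None = None
    diagnostics: dict = field(default_factory=dict)
    #: resident equilibrium at the SS on the demographic branch the search
    #: tracked (the frequency dynamics can be bistable: a cold re-solve may
    #: land in a different, possibly single-sex, basin)
    equilibrium: object | None = None

    @property
    def found(self) -> bool:
        return self.ss_type is not None

    def summary(self) -> str:
        if not self.found:
            return "No singular strategy found.\n" + str(self.diagnostics.get("sign_grid", ""))
        names = {
            1: "interior",
            2: "boundary s2=0",
            3: "boundary s2=1",
            4: "boundary s1=0",
            5: "boundary s1=1",
        }
        lines = [
            f"Singular strategy: Type {self.ss_type} ({names[self.ss_type]})",
            f"  s* = ({self.location.s1:.6f}, {self.location.s2:.6f})",
            f"  D(s*) = ({self.gradient_at_ss[0]:+.3e}, {self.gradient_at_ss[1]:+.3e})",
        ]
        if self.neutral_line:
            lines.append("  note: lies on a selectively neutral line")
        if len(self.candidates) > 1:
            lines.append(f"  {len(self.candidates)} candidate roots in total")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "ss_type": self.ss_type,
            "s1": None if self.location is None else self.location.s1,
            "s2": None if self.location is None else self.location.s2,
            "gradient": None
            if self.gradient_at_ss is None
            else [float(g) for g in self.gradient_at_ss],
            "neutral_line": self.neutral_line,
            "candidates": [
                {"ss_type": t, "s1": s.s1, "s2": s.s2} for (t, s) in self.candidates
            ],
        }


#: (type, fixed component index, fixed value, free component index, sign of the
#: fixed component's gradient required at the root)
_BOUNDARY_CASES = (
    (2, 1, 0.0, 0, -1.0),
    (3, 1, 1.0, 0, +1.0),
    (4, 0, 0.0, 1, -1.0),
    (5, 0, 1.0, 1, +1.0),
)

_INTERIOR_STARTS = (
    (0.5, 0.5),
    (0.3, 0.3),
    (0.7, 0.7),
    (0.3, 0.7),
    (0.7, 0.3),
    (0.15, 0.5),
    (0.85, 0.5),
    (0.5, 0.15),
    (0.5, 0.85),
    (0.62, 0.45),
)


def find_singular_strategy(
    model: TwoSexModel,
    mode: str = "literal",
    method: str = "finite-difference",
    grad_zero_tol: float = 1e-8,
    sign_tol: float = 1e-7,
    interior_margin: float = 1e-3,
    boundary_grid: int = 15,
) -> SingularStrategyReport:
    """Locate and classify a singular strategy by the five-step search.

    (1) multi-start root search for ``D = (0, 0)`` in the interior of the
    constraint box; (2–5) on each boundary in turn, a bracketing 1-D root
    search of the free component's gradient followed by a sign check of the
    fixed component's gradient.  The first satisfied case is returned; all
    roots encountered are kept in ``candidates``.
    """
    gf = _GradientField(model, mode=mode, method=method)

    _SENTINEL = np.array([1e3, 1e3])

    def D_and_eq(arr):
        """Gradient plus its resident equilibrium; None marks a strategy whose
        equilibrium is degenerate (single-sex) or failed — the gradient there
        vanishes trivially and must not be mistaken for a singular strategy."""
        arr = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(arr)):
            return None, None
        s = SexRatioStrategy(float(np.clip(arr[0], 0, 1)), float(np.clip(arr[1], 0, 1)))
        try:
            D, eq = gf(s)
        except TwoSexModelError:
            return None, None
        if not np.all(np.isfinite(D)) or equilibrium_is_single_sex(model, eq):
            return None, eq
        return D, eq

    def D_of(arr) -> np.ndarray:
        D, _ = D_and_eq(arr)
        return _SENTINEL if D is None else D

    candidates: list = []
    interior_roots: list[np.ndarray] = []
    eps = 1e-6
    # screen the multi-start grid first and descend only from the most
    # promising starts — gradient plateaus (degenerate regions) are expensive
    screened = []
    for x0 in _INTERIOR_STARTS:
        D0, _ = D_and_eq(np.asarray(x0))
        if D0 is not None:
            screened.append((float(np.max(np.abs(D0))), x0))
    screened.sort()
    for _, x0 in screened[:3]:
        try:
            sol = optimize.least_squares(
                D_of,
                np.asarray(x0),
                bounds=([eps, eps], [1 - eps, 1 - eps]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=None,
                diff_step=1e-5,
                max_nfev=60,
            )
        except TwoSexModelError:
            continue
        root = sol.x
        D_root, _ = D_and_eq(root)
        if (
            D_root is not None
            and np.max(np.abs(D_root)) < grad_zero_tol
            and np.all((root > interior_margin) & (root < 1 - interior_margin))
        ):
            if not any(np.max(np.abs(root - r)) < 1e-4 for r in interior_roots):
                interior_roots.append(root)
                candidates.append((1, SexRatioStrategy(root[0], root[1])))
        if interior_roots:
            break
    if interior_roots:
        root = interior_roots[0]
        s_star = SexRatioStrategy(float(root[0]), float(root[1]))
        D_root, eq_root = D_and_eq(root)
        return SingularStrategyReport(
            location=s_star,
            ss_type=1,
            gradient_at_ss=D_root,
            candidates=candidates,
            equilibrium=eq_root,
        )

    # keep the scan away from the inviable corners (0,0) and (1,1), where the
    # population degenerates to a single sex
    lo, hi = 0.005, 0.995
    sign_grids = {}
    first_hit: SingularStrategyReport | None = None
    for ss_type, fixed_idx, fixed_val, free_idx, needed_sign in _BOUNDARY_CASES:

        def g(x: float) -> float:
            arr = np.empty(2)
            arr[fixed_idx] = fixed_val
            arr[free_idx] = x
            D, _ = D_and_eq(arr)
            return np.nan if D is None else float(D[free_idx])

        grid = np.linspace(lo, hi, boundary_grid)
        vals = np.array([g(x) for x in grid])
        sign_grids[ss_type] = dict(zip(grid.round(4).tolist(), vals.tolist()))
        noise_floor = 1e-9  # finite-difference noise; not a meaningful sign
        for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if (
                np.isfinite(fa)
                and np.isfinite(fb)
                and min(abs(fa), abs(fb)) > noise_floor
                and np.sign(fa) != np.sign(fb)
            ):
                try:
                    x_root = float(optimize.brentq(g, a, b, xtol=1e-10, rtol=1e-12))
                except ValueError:
                    continue
            else:
                continue
            arr = np.empty(2)
            arr[fixed_idx] = fixed_val
            arr[free_idx] = x_root
            D_root, eq_root = D_and_eq(arr)
            if D_root is None:
                continue
            s_root = SexRatioStrategy(arr[0], arr[1])
            ok_free = abs(D_root[free_idx]) < max(grad_zero_tol, 1e-7)
            ok_fixed = (
                abs(D_root[fixed_idx]) > sign_tol
                and np.sign(D_root[fixed_idx]) == needed_sign
            )
            if ok_free and ok_fixed:
                candidates.append((ss_type, s_root))
                if first_hit is None:
                    first_hit = SingularStrategyReport(
                        location=s_root,
                        ss_type=ss_type,
                        gradient_at_ss=D_root,
                        candidates=candidates,
                        equilibrium=eq_root,
                    )
        if first_hit is not None:
            first_hit.candidates = candidates
            return first_hit

    return SingularStrategyReport(
        location=None,
        ss_type=None,
        gradient_at_ss=None,
        candidates=candidates,
        diagnostics={"sign_grid": sign_grids},
    )


@dataclass
class NeutralLineReport:
    """Multi-start trajectory evidence for a selectively neutral line.

    A neutral line is declared when trajectory endpoints are mutually distant
    in trait space (no unique attractor) yet all selection gradients have
    vanished; all endpoints then share the same union-weighted average sex
    ratio ``s̄``.
    """

    endpoints: list
    gradients: list
    s_bars: list
    is_neutral_line: bool
    s_bar_mean: float
    s_bar_spread: float
    max_pairwise_distance: float
    all_converged: bool
    separation_threshold: float = 0.05
    gradient_threshold: float = 1e-6
    #: fertility-weighted averages (male fraction among births); on a neutral
    #: line with unequal union fertilities this is the shared invariant
    s_bars_fertility: list = field(default_factory=list)
    s_bar_fertility_mean: float = np.nan
    s_bar_fertility_spread: float = np.nan

    def summary(self) -> str:
        lines = [
            f"Neutral-line scan over {len(self.endpoints)} trajectory starts",
            f"  endpoints pairwise separation (max) = {self.max_pairwise_distance:.4f}",
            f"  max |D|_inf over endpoints = "
            f"{max(float(np.max(np.abs(g))) for g in self.gradients):.3e}",
            f"  shared s_bar = {self.s_bar_mean:.6f} (spread {self.s_bar_spread:.2e})",
            f"  neutral line: {self.is_neutral_line}",
        ]
        for s, sb in zip(self.endpoints, self.s_bars):
            lines.append(f"    endpoint ({s.s1:.4f}, {s.s2:.4f})  s_bar = {sb:.6f}")
        return "\n".join(lines)


def detect_neutral_line(
    model: TwoSexModel,
    mode: str = "literal",
    n_starts: int = 5,
    seed: int = 0,
    separation: float = 0.05,
    gradient_tol: float = 1e-6,
    stop_tol: float = 1e-7,
    starts: list[SexRatioStrategy] | None = None,
) -> NeutralLineReport:
    """Integrate trajectories from several interior starts and test for a
    line of selectively neutral strategies.

    Declares a neutral line when endpoints are pairwise separated by more
    than ``separation`` in trait space while every endpoint's gradient norm
    is below ``gradient_tol``; reports the shared union-weighted average sex
    ratio and its spread either way.
    """
    if starts is None:
        if n_starts < 5:
            raise ValueError("need at least 5 interior starts")
        rng = np.random.default_rng(seed)
        pts = 0.1 + 0.8 * rng.random((n_starts, 2))
        starts = [SexRatioStrategy(float(a), float(b)) for a, b in pts]
    trajs = [
        integrate_strategy_trajectory(
            model, s0, mode=mode, stop_tol=stop_tol, gradient_tol=gradient_tol
        )
        for s0 in starts
    ]
    endpoints = [t.endpoint for t in trajs]
    grads = [t.gradient_at_end for t in trajs]
    sbars = [t.s_bar_at_end for t in trajs]
    sbars_fw = []
    for e in endpoints:
        eq = solve_equilibrium(model, e)
        sbars_fw.append(union_weighted_sex_ratio(model, e, eq, fertility_weighted=True))
    pts = np.array([[e.s1, e.s2] for e in endpoints])
    dmax = max(
        float(np.max(np.abs(pts[i] - pts[j])))
        for i in range(len(pts))
        for j in range(i + 1, len(pts))
    )
    all_small = all(float(np.max(np.abs(g))) < gradient_tol for g in grads)
    all_converged = all(t.converged for t in trajs)
    return NeutralLineReport(
        endpoints=endpoints,
        gradients=grads,
        s_bars=sbars,
        is_neutral_line=bool(dmax > separation and all_small and all_converged),
        s_bar_mean=float(np.mean(sbars)),
        s_bar_spread=float(np.max(sbars) - np.min(sbars)),
        max_pairwise_distance=dmax,
        all_converged=all_converged,
        separation_threshold=separation,
        gradient_threshold=gradient_tol,
        s_bars_fertility=sbars_fw,
        s_bar_fertility_mean=float(np.mean(sbars_fw)),
        s_bar_fertility_spread=float(np.max(sbars_fw) - np.min(sbars_fw)),
    )
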