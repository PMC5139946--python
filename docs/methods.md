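# Methods

This note documents the model assumptions, the numerical machinery and the
design decisions behind `twosex`, at the level of detail a user needs to
judge what a passing test does and does not establish.

## Demographic model

The state is a stage vector `n` over single males, single females and mated
unions; a union `u_ij` (condition-`i` male, condition-`j` female) is one
stage entity containing two individuals.  Dynamics are continuous-time,

    dn/dt = A(p) n,  A = (T + B + U)/3,

where `T` holds maturation, mortality, divorce and union-dissolution flows,
`B` holds births, and `U` holds union formation.  The 1/3 average is a
uniform rescaling of time: it changes `λ` by the same factor everywhere and
leaves equilibrium frequencies, eigenvector directions, selection-gradient
zeros and singular strategies untouched.

Two bookkeeping conventions are worth making explicit:

* **Entity vs individual accounting.**  Column sums of `U` over single-adult
  columns are not zero — two singles merge into *one* union entity.
  Individuals are conserved exactly when union stages carry weight 2:
  `zᵀU = 0` with `z = 1` on singles and `2` on unions.  The same weighting
  makes the union columns of `T` pure loss columns (divorce splits one
  entity into two singles, which is not a gain of individuals).  The
  package validates the weighted laws.
* **Orientation.**  `A[i, j]` is the per-capita rate of flow into stage `i`
  from stage `j` (column source, row destination).

Only unions reproduce.  The union's fertility `k_j` and primary sex ratio
`s_j` are those of its female member (maternal determination).

### Frequency dependence and equilibrium

All rates depend on `n` only through frequencies `p = n/‖n‖₁` (‖·‖₁ over
stage entities).  The simplex flow `dp/dt = (I − p·1ᵀ)A(p)p` converges to
`p̂`; `λ, w, v` are the dominant eigen-triple of `A(p̂)` with `w` normalized
to sum 1 (it equals `p̂`) and `v` scaled so `vᵀw = 1`.  Exponential growth or
decline of total size is irrelevant to the evolutionary analysis, so no
density dependence is modelled.

### Mating

The mating market consists of single adults only.  A chooser's preference
distribution over partner conditions is assortative, abundance-proportional
(random), or abundance-weighted by attractiveness factors `c_i` (biased;
equal factors reduce to random, a zero factor removes that condition from
the market).  Sex-specific availabilities (own density × partner's
preference for one's condition) enter a Hölder generalized weighted mean
with exponent `a < 0`; the package default, and the only member used by the
case studies, is the harmonic mean `M = 2xy/(x+y)` (`a = −1, b = ½`), which
vanishes whenever either sex's availability vanishes.  Per-capita rates are
`U_m = M/m_i`, `U_f = M/f_j`, defined as 0 on empty pools.  The generic
pipeline (preference → availability → mean → per-capita) and the closed
forms used in the case-study builders are verified against each other to
1e-12 in the test-suite.

## Adaptive dynamics

Residents with strategy `s = (s1, s2)` (proportion of sons per maternal
condition, each in [0,1], the corners (0,0) and (1,1) inviable) set the
environment through `p̂`.  Invasion fitness of a rare mutant `s′` is
`Λ = λ′(p̂) − λ`.

### Mutant construction

Two constructions of the mutant matrix `A′` are implemented:

* **literal** (default, the reference construction): `A′` is structurally
  identical to the resident matrix with `s′` substituted wherever the sex
  ratio appears, evaluated at the resident `p̂`.  Self-invasion neutrality
  `Λ_s(s) = 0` is immediate.
* **expanded**: a genetically explicit lineage bookkeeping.  The mutant
  subpopulation carries its own copies of all single stages plus two copies
  of each union type — mutant-male × resident-female (births at the
  *resident* female's sex ratio, and in the parental-mortality case her γ)
  and resident-male × mutant-female (births and γ at `s′`).  Requiring
  exact self-invasion neutrality pins the credit factors uniquely up to
  stage rescaling: union formation and dissolution returns at full rate,
  births of mixed unions credited at `k/2` — precisely Mendelian
  transmission of a rare dominant allele, half of whose carriers' mates'
  offspring inherit it.  With these factors the resident eigen-system lifts
  exactly onto the mutant block and neutrality holds to machine precision
  (tested in both modes).

The two modes weight the male and female transmission pathways differently,
so their selection gradients differ beyond a common factor.  For the
maternal-age case with equal fertilities the literal mode places the
neutral line's shared average sex ratio at 0.6043 ≈ Cf/(Cm+Cf), the
equal-investment value; the expanded mode places it at ≈ 0.572.  Because
the equal-investment prediction is the established benchmark for this
model family, the literal construction is the package default and the one
under which all acceptance results are computed; expanded mode is retained
as a switch (`mode="expanded"`) for sensitivity analysis.

### Gradients, trajectories, singular strategies

* **Selection gradient**: central finite differences of `λ′` with step 1e-6,
  switching to second-order one-sided stencils at the box boundary; and an
  independent eigen-sensitivity ("vec") route `D_k = v′ᵀ (∂A′/∂s′_k) w′`
  with `v′ᵀw′ = 1` and the same stencil on the matrix.  The two agree to
  1e-4 relative (tested on random scenarios); the direct route is the
  default.  `λ′` comes from a dense eigensolve of the (10–16)-dimensional
  mutant matrix, so finite-difference noise is ~1e-9 on the per-time scale;
  gradient zeros are declared below 1e-8.
* **Canonical equation** `ds/dt = V(s)Dᵀ(s)` with
  `V = diag(s1(1−s1), s2(1−s2))` (diagonal: no pleiotropy; vanishing on the
  boundary, which confines trajectories to the box — round-off excursions
  are clamped).  Integration is adaptive RK23 in geometrically growing time
  chunks; the resident equilibrium is re-solved at every gradient
  evaluation, warm-started from the previous `p̂`.  A trajectory stops when
  `‖ds/dt‖∞ < 1e-7` or `‖D‖∞ < 1e-6` — the second criterion catches
  arrival on a selectively neutral line, where `V` stays finite but
  selection has ceased.
* **Singular-strategy search**, in the order: (1) an interior root of
  `D = (0,0)` by bound-constrained least squares from a multi-start grid
  (the ten starts are screened by `‖D‖` first and descent runs from the
  three most promising); (2–5) on each boundary in turn (`s2=0`, `s2=1`,
  `s1=0`, `s1=1`), a sign-change scan of the free component's gradient over
  [0.005, 0.995] followed by Brent refinement, accepting the root only if
  the fixed component's gradient exceeds 1e-7 in the outward direction.
  The first satisfied case is returned; all roots encountered are kept in
  `candidates` because these models can possess more than one singular
  strategy.
* **Degenerate states.**  A strategy whose resident equilibrium has
  (effectively) lost one sex — adult frequency of either sex below 1e-6 —
  has an identically zero gradient for trivial reasons; such points are
  excluded as SS candidates and from root brackets.  The report carries the
  equilibrium actually used at the root, because the frequency dynamics can
  be bistable (a viable two-sex equilibrium coexisting with a single-sex
  collapse); re-solving cold from uniform can land in the other basin.
* **Neutral line detection**: trajectories from ≥5 seeded interior starts;
  a neutral line is declared when endpoints are pairwise separated by more
  than 0.05 in trait space yet all endpoint gradients are below 1e-6.
  These two thresholds, and the 0.01 band on the shared average sex ratio,
  are implementation choices calibrated to nothing — they encode
  "macroscopically spread, selection-free, demographically equivalent".

### Average primary sex ratio

The union-weighted average `s̄ = Σ_j s_j u_{·j} / Σ u` uses equilibrium
union frequencies.  When union types differ in fertility the quantity
conserved along a neutral line is the *fertility-weighted* average (male
fraction among births, weights `u_{ij} k_j`); the two coincide when all
fertilities are equal, which is the only configuration for which a
reference value (0.6) exists.  Both are available via
`union_weighted_sex_ratio(..., fertility_weighted=...)`; the neutral-line
report carries both, and the offspring-mortality-cost checks assert the
fertility-weighted spread (< 0.01 across starts; observed ~1e-6).

## Numerical solution of the equilibrium

The equilibrium solver layers cheap certifiers over a robust integrator:

1. explicit RK45 on the simplex in windows of 50 time units (growing to
   400), with the right-hand side evaluated on the normalized clipped state
   so `1ᵀdp/dt = 0` holds identically and round-off cannot drift the total;
2. after each window, a damped Newton polish (finite-difference Jacobian,
   least-squares fallback for the singular Jacobians of boundary fixed
   points) targeting residual ≤ 1e-10, attempted from the current state,
   from a dominant-eigenvector fixed-point iteration `p ← w(A(p))` (which
   cuts through power-law transients), and — when one sex's mass has
   dropped below 1e-3 — from the state projected onto the single-sex
   subspace;
3. every Newton solution is *accepted* only if the flow is locally
   attracted to it: fast path, the state coincides with the dominant
   eigenvector of `A` at itself (within 1e-7); otherwise the spectrum of
   the finite-difference flow Jacobian must have no eigenvalue with real
   part above 1e-8 beyond the neutral radial direction.  This rejects
   saddles (any eigenvector of `A(p)` is a fixed point of the flow) while
   tolerating the near-defective spectra of states close to a collapse
   threshold.

Convergence is declared on window-to-window change below 1e-10, on an
accepted Newton solution, or — at the 1e5 time cap — on a state whose eigen
residual is below 1e-8 and which matches the dominant eigenvector within
1e-6 (very slow transient tails can be demographically converged long
before the delta criterion certifies them).  Non-convergence raises with
the last state attached.  Equilibria satisfy `‖A(p̂)p̂ − λp̂‖∞ < 1e-8`,
`‖w − p̂‖∞ < 1e-6` and `|vᵀw − 1| < 1e-10`; the dominant eigenvalue must be
real to 1e-9 (essential nonnegativity), else a model violation is raised.

## Random scenario generation

`generate_scenario(case, seed)` draws rate-type parameters log-uniform
(mortalities, maturation, divorce on [0.05, 2]; fertilities/investment on
[0.25, 10] — an order of magnitude around the defaults, which sit at 0.1–1
per unit time with fertilities near 10) and probability-type parameters
uniform on their constraint sets (strategies inside the box with a 0.02
margin from the inviable corners; competitiveness `c1 ∈ (0.05, 0.5)` with
`c2 = 1 − c1`; inheritance `q ∈ [0.5, 0.98)`).  Draws are reproducible from
the seed.  With `require_viable=True` the same stream is rejection-sampled
until the equilibrium at the drawn strategy sustains both sexes — random
rate combinations can legitimately collapse to a single-sex population,
where sex-ratio evolution is vacuous.

What the generator emulates is the *parametric* diversity of the model
family, not data: there is no observation noise, no sampling variability,
no model misspecification.  A green property test therefore establishes
internal consistency (conservation laws, self-invasion neutrality, gradient
cross-validation, ordering theorems) across the parameter space, not
agreement with any empirical population.

## Known limitations

* For the maternal-age case with parental-mortality costs and *young*
  mothers more fertile (`k1 > k2`), the implemented model's five-step
  search and all canonical trajectories find a boundary SS at which *old*
  mothers specialize in the costlier sex (e.g. `s* = (0.855, 0)` for
  `Cm = 0.4, Cf = 0.6`) — the exact component mirror of the outcome usually
  quoted for this configuration (`s1* = 1` with `s2*` interior).  The
  mirrored configuration `k1 < k2` reproduces the quoted outcome exactly,
  and the selection along the near-neutral valley that decides between the
  two adjacent corner regimes is weak (gradients of order 1e-2).  The
  builder has been verified entry-by-entry against an independent
  transcription of the model matrices, and no member of the implemented
  mutant-bookkeeping family changes the sign; the discrepancy is recorded
  rather than patched.
* Evolutionary and convergence stability of vector-valued singular
  strategies is assessed empirically (trajectory convergence), not by a
  formal second-order criterion; after evolutionary branching nothing here
  applies (no polymorphic residents).
* Uniqueness of the demographic equilibrium is not guaranteed; the solver
  tracks the branch reached from its start (warm starts track branches
  continuously), multi-start tests probe for non-uniqueness, and bistable
  strategy regions are handled by reporting the branch used.
* The boundary scan uses 15 grid points on [0.005, 0.995]; a gradient root
  whose bracket is narrower than the grid spacing, or closer than 0.005 to
  an inviable corner, would be missed.
* Mating preferences are condition-local (abundance- or
  attractiveness-weighted); ranking rules that depend on the global
  population composition are out of scope, as are paternal-condition sex
  ratios and costs of switching sex ratios between conditions.
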