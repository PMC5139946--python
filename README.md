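# twosex

Frequency-dependent two-sex matrix population models and the adaptive
dynamics of facultative (condition-dependent) sex ratios.

Many species adjust the sex ratio of their offspring according to a maternal
condition — age, body size, social rank, resource holdings.  Young and old
mothers may use different sex ratios; the Trivers-Willard hypothesis predicts
that high-quality mothers bias production toward the sex whose reproductive
success rises more steeply with quality.  Modelling the evolution of such
strategies needs two ingredients that most sex-ratio theory omits: explicit
two-sex demography (sons are only worth what their mating opportunities make
them worth) and a multidimensional trait (one sex ratio per maternal
condition).  `twosex` provides both, for theoretical population biologists
who want singular strategies of structured two-sex models computed from
parameter values alone.

## The model

A population vector `n` counts single males and females by condition plus
mated unions `u_ij` (condition-`i` male with condition-`j` female) as
explicit stages.  Transitions `T`, births `B` and union formation `U` are
continuous-time rate matrices whose average is the projection matrix

    dn/dt = A(p) n,   A = (T + B + U)/3,

with every rate depending on the population only through the stage
frequencies `p = n/‖n‖`.  Union formation uses harmonic-mean mating
functions on preference-weighted availabilities (`M = 2xy/(x+y)`, the
`a = −1, b = ½` member of the Hölder family), so reproduction vanishes as
either sex becomes rare.  The frequency dynamics
`dp/dt = (I − p·1ᵀ) A(p) p` converge to an equilibrium `p̂`; the population
then grows at `λ`, the dominant eigenvalue of `A(p̂)`, whose left eigenvector
`v` carries stage-specific reproductive values.

The evolving trait is the bivariate primary sex ratio `s = (s1, s2)` —
proportion of sons produced by condition-1 and condition-2 mothers.  A rare
mutant playing `s′` in the resident's equilibrium environment grows at `λ′`;
invasion fitness is `Λ_s(s′) = λ′(p̂) − λ` and the selection gradient
`D(s) = ∂λ′/∂s′|_{s′=s}` drives the canonical equation

    ds/dt = V(s) Dᵀ(s),   V(s) = diag(s1(1−s1), s2(1−s2)),

whose mutational variance vanishes on the boundary of the unit box.
Stationary points are singular strategies (SSs): one interior type (both
gradient components zero) and four boundary types (one component pinned at
0 or 1 with the gradient pointing out of the box).  Some parameter regions
instead produce a whole *neutral line* of strategies sharing one average
sex ratio — the package detects these by trajectory multi-starts.

Two case studies ship ready-made:

* **Maternal age** (10 stages): juveniles, young/old adults, four union
  types.  Offspring can be costly through parental mortality
  (`γ_j = β k_j (s_j C_m + (1−s_j) C_f)` added to both partners of a
  reproducing union) or through offspring mortality during investment
  (fertility `k_j = R_j/(s_j C_m + (1−s_j) C_f)`).
* **Maternal quality** (12 stages, the Trivers-Willard setting): quality is
  transmitted maternally (`q ≥ 0.5`), females prefer competitive males
  (weights `c1 < c2`), high-quality females may invest more (`R2 > R1`).
  Diagnostics include the male/female reproductive value ratios
  `MRVR = v(m02)/v(m01)`, `FRVR = v(f02)/v(f01)` and the equal-investment
  identity `Cm/Cf = v_m0/v_f0` at interior SSs.

## Worked example

Low-quality males win only 10% of the mating competition (`c1 = 0.1`),
females of both qualities invest equally (`R1 = R2 = 15`):

```python
from twosex import (maternal_quality_model, find_singular_strategy,
                    reproductive_value_ratios)

model = maternal_quality_model(R1=15, R2=15, c1=0.1)
report = find_singular_strategy(model)
print(report.summary())
rvr = reproductive_value_ratios(report.equilibrium)
print(rvr.summary())
```

prints

```
Singular strategy: Type 3 (boundary s2=1)
  s* = (0.160025, 1.000000)
  D(s*) = (+1.164e-10, +1.084e-02)
Reproductive value ratios
  juvenile males   v(low) = 0.295791, v(high) = 0.617658
  juvenile females v(low) = 0.378308, v(high) = 0.464414
  MRVR = 2.08816, FRVR = 1.22761  ->  MRVR>FRVR
```

High-quality mothers evolve to produce only sons (`s2* = 1`; the gradient's
second component is positive, pressing against the boundary) while
low-quality mothers are strongly daughter-biased (`s1* = 0.16`).  That is
the Trivers-Willard pattern, and the reproductive-value ratios confirm its
premise: male reproductive value rises about 2.1-fold from low to high
quality, female only 1.2-fold, so sons are the high-variance sex.

## Command line

Every analysis is also a CLI task over TOML configs, with packaged scenarios
for the standard figures of both case studies:

```
twosex ss-search --case case1a --set k1=5 --set k2=15 --set Cm=0.4 --set Cf=0.6
twosex reproduce fig4 --out results/          # neutral-line scan
twosex reproduce fig8a --out results/         # competitiveness sweep (CSV)
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantitative
results from scratch — the shared average sex ratio on the maternal-age
neutral line, the boundary singular strategies of both case studies under
unequal fertilities/competitiveness/investment, the reproductive-value-ratio
degeneracy under full symmetry, and the high-inheritance limit — and writes
them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The seed only affects the random interior starts of the trajectory scan;
all other computations are deterministic.
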