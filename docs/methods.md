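# Methods

## Model

Two habitat patches exchange prey by random migration; each patch holds a
resident predator. With prey biomasses `x, y`, predator biomasses `z, w`:

```
x' = φ₁(x,z)·x + σ₂y          φ₁ = r − σ₁ − q₁E₁ − m₁z − rx/K
y' = σ₁x + φ₂(y,w)·y          φ₂ = s − σ₂ − q₂E₂ − m₂w − sy/L
z' = φ₃(x,z)                  φ₃ = α₁z(1 − z/(γ₁x))
w' = φ₄(y,w)                  φ₄ = α₂w(1 − w/(γ₂y))
```

Assumptions: logistic prey growth in the absence of predation; harvesting
proportional to effort and stock (catch-per-unit-effort); Leslie–Gower
predators whose local carrying capacity tracks prey abundance (`γᵢ` is the
equilibrium predator-to-prey ratio); only prey migrate. The formulation
follows the published model exactly, including its asymmetry: the prey
functionals multiply the biomass while the predator functionals enter as
whole right-hand sides (for the Leslie–Gower form the two conventions
coincide since φ₃ already contains the factor z). The predator terms are
evaluated in the factorized form `α z (1 − z/(γx))`, which vanishes
exactly (in floating point) on the nullcline `z = γx` and avoids the
cancellation of the expanded `αz − αz²/(γx)`.

The domain of the vector field is `x > 0, y > 0`: the predator equations
divide by prey biomass. Deterministic integrators treat prey at or below
a floor of 1e-12 as leaving the model's domain and halt with a
diagnostic rather than continuing silently.

### Parameters and presets

| name | meaning | unit | table1 | figset |
|------|---------|------|--------|--------|
| r, s | prey intrinsic growth | 1/time | 3, 2.8 | 3, 3.2 |
| σ₁, σ₂ | migration 1→2, 2→1 | 1/time | 1.8, 1.6 | same |
| q₁, q₂ | catchability | 1/(effort·time) | 0.5, 0.7 | same |
| E₁, E₂ | harvesting effort | effort | 2.5, 3.5 | 0.9, 1.2 |
| m₁, m₂ | predation rate | 1/(predator·time) | 1.2, 1.8 | same |
| γ₁, γ₂ | predator/prey equilibrium ratio | — | 0.5, 0.3 | 0.5, 0.2 |
| K, L | prey carrying capacity | biomass | 10, 15 | same |
| α₁, α₂ | predator intrinsic growth | 1/time | 0.5, 0.8 | same |

The two published parameter listings disagree in four entries, so both
ship as named presets and every report records which was used. `figset`
is the set quoted alongside the deterministic time-series experiments;
`table1` is the tabulated set, which the noise-intensity and delay
experiments reference. Parameter validation requires strict positivity
except for σ and m, which may be zero (the migration-free, predation-free
reductions are used as test oracles).

## Interior equilibrium

Setting the predator equations to zero at positive prey forces
`z* = γ₁x*`, `w* = γ₂y*`. Substituting into the prey equations and
writing `R₁ = r − σ₁ − q₁E₁`, `R₂ = s − σ₂ − q₂E₂`, `M₁ = m₁γ₁ + r/K`,
`M₂ = m₂γ₂ + s/L` gives the patch-1 nullcline
`y = x(M₁x − R₁)/σ₂` and, after substitution into the patch-2 nullcline
and division by x, the cubic

```
a₃x³ + b₃x² + c₃x + d₃ = 0
a₃ = M₁²M₂/σ₂²          b₃ = −2R₁M₁M₂/σ₂²
c₃ = R₁²M₂/σ₂² − M₁R₂/σ₂   d₃ = R₁R₂/σ₂ − σ₁
```

The re-derived c₃ above is authoritative: the published closed form has
unbalanced parentheses (it reads as if only the s/L part of M₂ multiplied
R₁²), while a₃, b₃, d₃ match the published forms exactly. The literal
variant is retained behind `mode="paper_literal"` so the discrepancy can
be displayed rather than silently corrected. A unit test checks the
derived cubic against direct nullcline substitution at arbitrary points.

Roots are taken from the companion matrix (`numpy.roots`), each positive
real root with positive `y` is polished by Newton iteration on the
reduced 2-D prey system (stop at residual 1e-12 or 50 iterations), and
the result is accepted only if the **full** four-species vector field is
below 1e-8 in max-norm. If several admissible roots survive, all are
available (`return_all=True`) and the smallest-x* one is designated
primary; if none survive, a distinct `NoInteriorEquilibrium` outcome is
raised, separate from numerical failure. An independent scipy `hybr`
2-D solve (`solve_equilibrium_direct`) provides a second route used by
the oracle-equivalence tests (relative agreement 1e-6).

The two published existence inequalities — `R₁²M₂ < M₁σ₂R₂` and
`R₁R₂ < σ₁σ₂` — and the positivity bound `x* > R₁/M₁` are evaluated
verbatim and reported; they never gate the solver. (`figset` satisfies
both; `table1` violates the first because `R₂ = −1.25 < 0`, yet still has
a unique admissible equilibrium — the conditions are sufficient, not
necessary.)

## Local stability

The characteristic polynomial `λ⁴ + a₁₁λ³ + a₂₂λ² + a₃₃λ + a₄₄` is
computed from the analytic Jacobian (`numpy.poly`), so `a₁₁ = −tr J` and
`a₄₄ = det J` by construction. The published closed forms for the
coefficients are implemented as a diagnostic `paper_literal` mode: a₁₁
and a₂₂ reproduce the derived values to machine precision, while a₃₃ and
a₄₄ differ (≈4% and ≈8% on `figset`) — the published a₃₃ contains the
token `a₁α₁α₂` (read here as `a·α₁α₂`) and a missing `+`, and the
published a₄₄ repeats the term `α₁α₂rσ₁x*²/(Ky*)`. `charpoly_comparison`
quantifies the gaps; the derived path is used everywhere else.

The five published Routh–Hurwitz conditions are evaluated exactly as
stated and cross-checked against the eigenvalue verdict; the two are
mathematically equivalent for quartics, so any mismatch is treated as a
bug. When an eigenvalue's real part is within 1e-9 of zero the verdict is
flagged indeterminate instead of forcing agreement.

## Global stability (Lyapunov)

`V = f(x;x*) + l₁f(y;y*) + l₂f(z;z*) + l₃f(w;w*)` with
`f(u;u*) = u − u* − u* ln(u/u*)`, weights `l₁ = (y*/x*)(σ₂/σ₁)`,
`l₂ = 1/α₁`, `l₃ = 1/α₂`. The prey box is

```
A,B = (1 + 2c ∓ √(4c + 4c²))/m₁,          c = r/(m₁Kγ₁)
C,D = pref·(1 + 2d ∓ √(4d + 4d²)),        d = s/(Lγ₂m₂),  pref = σ₁x*/(m₂σ₂y*)
```

`(1+2c)² > 4c+4c²` guarantees `0 < A < B` (likewise C, D) for every
positive parameter set, which the property tests quantify over the random
sampler. The published derivative expression mixes signs and appears to
double-count one cross term, so the package does not assert `dV/dt < 0`
analytically; instead `vdot_diagnostic` evaluates `∇V·f` exactly and
`vdot_box_census` samples the box (predators in 0.5–1.5 × their
equilibrium values — the theorem constrains only prey, so a band must be
chosen; it is recorded in the census metadata). On `figset` the census
finds `dV/dt < 0` at every one of 10⁴ sampled points. Note a caveat the
census makes visible: for `figset` the box does **not** contain the
equilibrium's patch-2 prey level (y* = 3.83 > D = 2.06), so V need not
decrease monotonically along whole trajectories; the trajectory-level
test asserts monotone decrease only on steps whose prey lie inside the
box.

## Stochastic analysis

Additive Gaussian white noise `βᵢξᵢ(t)` enters each equation;
`simulate_sde` uses Euler–Maruyama (exact in the noise term for additive
noise) at dt = 1e-3 by default. In the stochastic integrator **all four**
components are clamped at the 1e-12 floor: at the largest study
amplitudes (β up to 200) the noise dwarfs the drift, prey repeatedly
touch zero, and an unclamped predator then blows up through `z²/x`.
Clamp events are counted in the trajectory metadata.

The linearized perturbation system is implemented exactly as published:
the drift keeps the predation couplings and the diagonal decay terms
`−N₁S*`, `−N₂P*`, `−N₃T*/S*²`, `−N₄U*/P*²` (`N₁ = r/K`, `N₂ = s/L`,
`N₃ = α₁/γ₁`, `N₄ = α₂/γ₂`) but omits the migration couplings σ₁, σ₂ and
part of the prey self-limitation present in the full Jacobian. Whether
that omission is a deliberate block approximation or an error cannot be
settled here; both matrices are computed and `linearization_gap` reports
the entrywise difference, while the spectral machinery stays faithful to
the published system. A useful structural consequence: the published
drift is block-diagonal over {x,z} × {y,w} with each 2×2 block provably
Hurwitz for any positive equilibrium, so the spectral pipeline is always
well-posed.

`M(ω) = iωI − drift`, `G = M⁻¹` by LU inversion (the published adjugate
closed forms contain evident typos and are used only for the
structural-zero checks: the eight entries published as identically zero
are verified to vanish below 1e-12). Spectra default to
`S_uᵢ(ω) = Σⱼ βⱼ²|gᵢⱼ|²`; the published form sums `βⱼ|gᵢⱼ|²` and is kept
as `mode="paper_literal"` (a flat-spectral-density-β versus β² bookkeeping
difference; the squared form is the standard white-noise result and makes
variances scale exactly quadratically in each amplitude).

Stationary variances are computed two independent ways and
cross-checked to 1%:

1. **Frequency quadrature**: `σᵢ² = (1/π)∫₀^∞ S_uᵢ dω` via adaptive
   `scipy.integrate.quad`, with the truncation Ω doubled until the
   closed-form tail `βᵢ²/(πΩ)` (from `|gᵢᵢ| → 1/ω`) is below 0.1%, then
   added analytically. The quadrature is anchored at every spectral scale
   of the drift (|Re λ|, |Im λ|, |λ| and small multiples): sampled
   parameter sets can put a Lorentzian of width ~1e-4 under a truncation
   of ~1e4, which an unanchored adaptive rule misses entirely.
2. **Covariance route**: `scipy.linalg.solve_continuous_lyapunov` on
   `AP + PAᵀ + diag(β²) = 0`; the diagonal of P is the variance vector.

Validation anchors: a scalar Ornstein–Uhlenbeck embedding
(`u' = −au + βξ` in one slot of the 4×4 machinery) reproduces
`σ² = β²/(2a)` to 1e-12 and the autocorrelation `e^{−a|τ|}` to 1e-3; the
band-averaged periodogram of a long (T = 4000) linearized simulation
tracks the analytic spectra within ±20% across each population's dominant
band. The empirical periodogram uses `scipy.signal.periodogram`
(boxcar, mean removed) mapped to the angular-frequency convention
`variance = (1/π)∫₀^∞ S dω`; autocovariances come either from the cosine
transform of a spectrum grid or from the sample autocovariance of a
trajectory, normalized so P(0) = 1.

The qualitative noise-intensity experiment is made quantitative by
`noise_variance_scan`: the five study amplitude sets (1.5,1,1.5,1) →
(200,150,200,150) are simulated with **paired seeds** (identical Brownian
increments per replicate across sets, 20 replicates, t_end = 50,
`table1`, started at the equilibrium) and the late-window
([0.8,1]·t_end) sample variance of every population is checked to be
non-decreasing across the sets.

## Delay

The gestation delay enters the predation products. The published
formulation, "m₁ z x(t−τ)", is token-ambiguous between lagging the prey
factor, the predator factor, or the whole product; all three are
implemented (`delayed="prey" | "predator" | "product"`). The default is
the **predator-lagged** reading `m₁z(t−τ)x(t)`, chosen on three grounds:

1. It matches the stated motivation — consumed prey takes time to become
   predation pressure.
2. It is the only reading that preserves the positive orthant: in the
   prey-lagged and product readings the delayed removal term
   `−m₁z·x(t−τ)` does not shrink with the current prey, and prey biomass
   is driven through zero (verified both by stiff integration with
   zero-crossing events and by the characteristic roots below).
3. Linear analysis of `det(λI − J₀ − J_d e^{−λτ}) = 0` at the `table1`
   equilibrium gives, under the predator-lagged reading, a rightmost root
   of −0.030 at τ = 2.5 and +0.038 at τ = 12.5 — a small-delay stable
   regime and a large-delay oscillatory regime, which is the observed
   phenomenology. Under the prey-lagged reading the equilibrium is
   already unstable at τ = 2.5 (root +0.22 at `table1`, +0.45 at
   `figset`) for **both** presets, leaving no stable small-delay regime
   at all.

The delay experiments use the `table1` preset (the published account of
the noise and delay experiments points to the tabulated values; under
`figset` the decay rate at τ = 2.5 is only −0.006/time — a transient that
has not settled by t = 500 — whereas `table1` decays five times faster
and reproduces the reported regimes robustly).

No initial function is published for the delay runs, and the
biomass-scale guesses far from equilibrium collapse the prey (point 2
above). The default constant history is therefore a 5% multiplicative
kick off the interior equilibrium — the standard probe of delay-induced
local instability; it is configurable.

Integration is by the method of steps: classical RK4 with the step
adjusted so `τ/dt` is an integer (exact grid lookup for whole-step lags),
and the half-stage lag — always exactly midway between grid nodes —
interpolated by a fixed-weight cubic Lagrange stencil ([−1,0,1,2] around
the lag node; one-sided for τ = dt). At τ = 0 the code dispatches to the
same RK4 stepper on the undelayed field, so the reduction is exact.
Defaults for the study runs: dt = 0.005, t_end = 500 (1e5 steps, ≈2 s per
delay), sizes chosen so the four-delay scan stays interactive.

The classifier measures peak-to-trough ranges per population in a mid
window [0.4,0.6]·t_end and a late window [0.8,1.0]·t_end:

* **convergent** — every population's late range < 1e-3 relative to the
  equilibrium magnitude;
* **sustained_oscillatory** — every population's late range above that
  tolerance **and** late/mid ratio ≥ 0.8 (no decay);
* **damped_oscillatory** — anything in between.

The thresholds are configurable; the defaults separate the synthetic
fixtures (constant, decaying sinusoid, steady sinusoid) and the extreme
study delays unambiguously. On `table1` with the default history the scan
labels τ = 2.5 convergent (late amplitude ≈ 9e-7 relative) and τ = 10.5,
11.5, 12.5 sustained (amplitude ratios ≈ 1.0). The published account
describes τ = 10.5 as eventually settling and τ = 11.5 both as a limit
cycle and as converging; neither label is asserted here — the scan simply
reports what the trajectories do, and under this model both delays sit
well above the computed stability boundary. `hopf_locate` bisects the
sustained/not-sustained boundary (damped counts as the stable side) and
brackets the critical delay near τ ≈ 3.0–3.2 at `table1`, consistent with
the characteristic-root crossing between τ = 2.5 and τ = 4.

## Random-parameter sampler

Property tests draw parameter sets log-uniformly within ±1 decade of the
`figset` values, rejecting sets without a positive interior equilibrium
(~90% retention; the fraction is recorded on the sampler). This spans
three orders of magnitude per parameter while staying in the regime where
the biomass scales are meaningful.

## What the tests do and do not show

All experiments here are synthetic: the model is the object of study and
there is no fitting to catch data. Passing tests demonstrate internal
mathematical consistency (dual-route agreements, exact reductions,
closed-form limits) and that the implemented dynamics reproduce the
qualitative regime structure at the study parameter sets — not that the
model describes any particular fishery. Known limitations: boundary
equilibria (any population extinct) are out of scope; the delay system is
analysed numerically only (no transcendental characteristic-equation
machinery); noise is additive only, so Itô and Stratonovich readings
coincide and no demographic (state-dependent) noise is offered; the
`paper_literal` modes reproduce published formulas for traceability, not
for use.
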