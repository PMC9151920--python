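# Methods

## The growth law

`xlogistic` models the density `x(t)` of a proliferating cell population in
culture by an extended logistic law,

    dx/dt = f(x) = r_p x^(α+1) (1 − (x/K)^β) − n x^(δ+1),

with six parameters ("the hexad"):

| parameter | meaning | units | typical fitted value |
|---|---|---|---|
| `r_p` | constant intrinsic proliferation rate | /h | 0.13 |
| `K` | carrying capacity | scaled density | 1.4–3.4 |
| `n` | negative-feedback rate from growth-inhibiting molecules | /h | 0.01–0.08 |
| `α` | cell–cell cooperation regulator: the intrinsic rate is `r_p x^α` | – | 0.4–1.2 |
| `β` | allometric crowding / environmental-resistance exponent | – | 1.0–1.4 |
| `δ` | regulation of the cell–inhibitor interaction: feedback is `n x^(δ+1)` | – | 0.07–0.2 |

The density scale is arbitrary (the assays the model was designed for report
scaled image-derived densities), so the package is unit-agnostic in `x`.

With `n > 0` and `α > δ` the law behaves like a strong Allee model: `x = 0`
is stable, an interior unstable equilibrium acts as a threshold below which
the population decays, and the largest stable equilibrium — the *conditional
maximum sustainable stable cell density* (MSSCD) — sits below `K` because of
the feedback term. The density at which the relative proliferation rate
(RPR, `f(x)/x`) peaks serves as a fitness measure for the population.

### Equilibria and numerical root finding

Interior equilibria and inflection points are roots of `f` and `f'`. Both
are located by scanning a composite grid of ≥ 2000 points — half log-spaced
on `(10⁻⁸K, 0.2K]`, half linear up to `search_upper` (default `3K`) —
because the Allee threshold can sit two orders of magnitude below `K`.
Every sign-change bracket is polished by Brent's method to `|Δx| ≤ 10⁻¹²K`,
so reported equilibria satisfy `|f| ≤ 10⁻⁹ max(1, r_p K^(α+1))`. Stability
of interior roots uses the sign of `f'`; the boundary equilibrium at 0 is
classified by the sign of `f` at `10⁻⁶K`, since `f` need not be
differentiable at 0 when `δ < 1`.

### Series approximations about K

Quadratic expansion of `f` about `x = K` yields closed forms for the two
interior equilibria (a minus/plus branch pair) and, at first order, for the
RPR argmax. These are exposed as explicit `*_approx` operations, separate
from the numeric roots, because their quality degrades away from `K`: for
the seeding-1 fitted hexad the minus branch reproduces the MSSCD to four
decimals (1.3507) while the plus branch gives 0.243 against a true
threshold of 0.0671. `threshold_approx` therefore returns the companion
numeric root alongside the series value. A negative discriminant is
reported as a typed "no MSSCD" result — this is a real region of parameter
space (strong feedback regulation δ with weak crowding β), not an error.

For `α = δ` the feedback folds into the growth term and the analysis is
exact: equilibria are `{0 (unstable), K(1 − n/r_p)^(1/β) (stable)}` for
`r_p > n`, and the RPR peaks at `K((r_p−n)α / (r_p(α+β)))^(1/β)`.
`max_rpr_density_approx` returns this exact form when `α = δ` and the
first-order expansion otherwise; the general expansion does *not* reduce to
the exact form in that limit, so switching branches is the correct
behaviour, and the result carries an `exact` flag.

### Trajectories

`solve_trajectory` integrates `f` with adaptive RK45 at `rtol 10⁻⁹ /
atol 10⁻¹²`, clipping densities at 0 from below. Tolerances are tight
enough that results are solver-independent at the 4-decimal level used
throughout.

## Fitting

Following the scratch-assay protocol the model was designed around
(replicated density measurements at 15 time points per seeding condition),
fitting happens on the *density–RPR profile*:

1. replicates are averaged per time point;
2. Fisher relative growth rates `RPR_i = (ln x̄_{i+1} − ln x̄_i) / Δt_i`
   are computed for consecutive pairs;
3. each increment is paired with a representative density — the arithmetic
   midpoint by default. The pairing is a genuine degree of freedom the
   protocol leaves open, so it is exposed as a policy
   (`left | midpoint | geometric_mean`); midpoint is the standard centred
   choice.

The hexad is then chosen by exhaustive search over a Cartesian parameter
grid, minimising `Σ (RPR_i − f(x_i)/x_i)²`. With 15 observations and six
parameters, gradient-based nonlinear least squares is poorly determined;
the grid search is the protocol. Ties are broken by lexicographically
smallest grid indices in `(r_p, K, n, α, β, δ)` order, making the result
independent of evaluation order. The RPR model separates as
`r_p x^α · b(K, β) − n x^δ`, so for each `(K, β)` block the RSS over all
`(r_p, α) × (n, δ)` combinations decomposes into `|u|² + 2u·v + |v|²`
pieces evaluated with two small matrix products; the shipped 10⁶-hexad
grids run in well under a second with a streaming arg-min (nothing is
materialised). A logistic baseline (`α = 0, β = 1, n = 0`) runs through the
same machinery for model comparison; grid refinement is left to the user.

`rss_density` scores a hexad on the time–density profile by integrating the
law from the first observed mean density (the protocol never states the
initial condition; the first observation is the natural default and is
overridable).

## Stochastic analog

Heterogeneity of the growth-inhibiting molecules enters as multiplicative
noise on the feedback rate (`n → n + ε(t)`), environmental fluctuation as
additive noise `Γ(t)`; both are zero-mean Gaussian white noises with
`⟨εε'⟩ = 2D δ(t−t')`, `⟨ΓΓ'⟩ = 2Q δ(t−t')` and cross-correlation
`2λ√(DQ) δ(t−t')`, giving the Stratonovich SDE

    dx/dt = f(x) − x^(δ+1) ε(t) + Γ(t).

Adiabatic elimination yields a one-dimensional Fokker–Planck equation
`∂P/∂t = −∂[A P]/∂x + ∂²[B P]/∂x²` with

    A(x) = f(x) + D(δ+1) x^(2δ+1) − λ√(DQ) (δ+1) x^δ
    B(x) = D x^(2δ+2) − 2λ√(DQ) x^(δ+1) + Q,

`B ≥ (1−|λ|)(D x^(2δ+2) + Q) ≥ 0` by AM–GM. The stationary density is
`P_st(x) = N/B · exp(∫ A/B)`; `stationary_pdf` accumulates `log P` by
trapezoid quadrature of `A/B`, exponentiates after subtracting the running
max, and normalises on `(0, x_max]` with `x_max` (default `3K`) raised
automatically until `P(x_max) < 10⁻¹⁰ max P` — a numerically faithful
truncation of the infinite-range normalisation. Extrema of `P_st` solve
`A − B' = 0` and reuse the equilibrium root-finder. The first-order
stochastic MSSCD expansion about `K` is implemented with the cross
amplitude `λ√(DQ)` in every term, including the second-order maximality
condition (one printed source form contains a `√(Dα)` that is
dimensionally inconsistent with the surrounding terms and with the
`α = δ` variant; `√(DQ)` is the coherent reading).

At `|λ| = 1`, `B` is a perfect square with an interior zero; the quadrature
then floors `B` at `10⁻¹² max(Q, D, 1)` and flags the result
(`regularized`), or raises if regularisation is disabled.

### Simulation

`simulate_ensemble` offers two routes that are statistically equivalent at
small `dt`:

* **`ito_equivalent`** (default): Euler–Maruyama on
  `dx = A dt + √(2B) dW` — the Itô diffusion whose Fokker–Planck equation
  is *exactly* the one above, so terminal distributions are directly
  comparable with `stationary_pdf`. This consistency is what the
  ensemble-vs-analytic check requires.
* **`stratonovich_heun`**: Heun predictor–corrector on the original
  two-noise form with Cholesky-correlated increments
  `dW₂ = λ dW₁ + √(1−λ²) dW₃` and amplitudes `√(2D)`, `√(2Q)`. Used as a
  cross-check; at `n = 2000` paths the two schemes agree to a two-sample
  sup-distance ≤ 0.06.

Default `dt = 10⁻³ h`; halving `dt` changes the terminal-density KS
distance by < 0.01 at the settings used in the tests. Ensembles are
bitwise-reproducible from `(seed, dt, scheme, params)`.

**Boundary at `x = 0`.** Two behaviours are provided because they answer
different questions:

* `reflecting` (`x ← |x|`, the default) is the boundary consistent with the
  stationary density, which is normalised on `(0, x_max]`. Use it when
  comparing terminal distributions against `stationary_pdf`.
* `absorbing` freezes a path at 0 once its density reaches 0: a well with
  no cells cannot be re-seeded by environmental fluctuation. This is the
  regime in which sustained extinction modes form. Under reflection the
  additive noise (`B(0) = Q > 0`) constantly kicks paths off zero, making
  the extinction region effectively repulsive: at the fitted seeding-1
  hexad with `D = Q = 0.01` the stationary mass below `0.05K` is only
  ≈ 2–3% for any λ, so no reflecting ensemble — transient or stationary —
  ever shows a dominant zero mode. Steady-state mode-structure studies
  therefore use the absorbing boundary.

### Mode-structure study design

The steady-state modality study runs 500 absorbing paths per configuration
from `x0 = MSSCD` for `T = 150 h` at `dt = 2×10⁻³ h` (the deterministic
relaxation time at the MSSCD is ≈ 5 h, so this is ≈ 30 relaxation times),
with extinction cutoff `0.05K`. Modes are local maxima of the terminal
histogram (Freedman–Diaconis bins plus a dedicated extinction bin) with
prominence ≥ 10% of the tallest bin. At the fitted seeding-1 hexad:

* `λ = 1, D = Q = 0.01`: `B` vanishes at `x = (Q/D)^(1/(2δ+2)) = 1`, below
  which drift is positive — the population cannot leak out. Unimodal,
  near-symmetric around the MSSCD, extinction mass ≈ 0.
* `λ = 0`: no noise quenching; extinction mass ≈ 0.5 by `T = 150` and the
  extinction bin is the dominant mode of a bimodal histogram.
* `D = 0.05, λ = 0.5, Q = 0.01`: strongest leak; extinction dominates
  (mass ≈ 0.6–0.7) and the surviving paths usually fail the prominence
  test, leaving a single extinction mode.
* `D = 0, λ = 0.5, Q = 0.01`: smallest extinction mass of the leaky
  configurations, with a clear surviving mode at the MSSCD.

A caveat this package states plainly: under the self-consistent dynamics
above, the escape-barrier integrals `∫ A/B dx` between threshold and MSSCD
differ little across these configurations (≈ 1.9–2.6), because raising `D`
raises the stabilising noise-induced drift along with the diffusion. The
*ordering* of extinction rates (λ=1 ≪ D=0 < λ=0 < D=0.05) is robust, but
the `D = 0` configuration still loses ≈ 25% of paths to extinction by
`T = 150 h` — additive-noise escape is genuinely not negligible at
`Q = 0.01` (barrier ΔU/Q ≈ 2.2) — so its histogram carries a secondary
extinction mode rather than being strictly unimodal. No common horizon
eliminates it without also erasing the extinction modes of the other
configurations.

## Synthetic assay generator

`synth_timeseries` emulates the assay design the fitting protocol assumes:
3 seeding conditions × 3 replicates, observations every 2 h to 18 h then
every 6 h to 48 h (15 time points). Densities are noiseless trajectories of
the law plus iid additive Gaussian observation noise per replicate,
truncated at 0, with sd defaulting to 0.02 (≈ 1–2% of a typical `K`; the
true assay error magnitude is unknown, so this is a labelled placeholder).
Initial densities default to `(0.1, 0.15, 0.2)`, loosely mirroring the
12k/16k/20k cells-per-well seeding ratios; the model's density scale is
arbitrary, so these are conventions, not calibrations. Noise applies to
densities only, never times; generation is deterministic given the seed.

What the generator does *not* emulate: spatially structured measurement
error, replicate-level batch effects, or any misfit between the growth law
and real proliferation kinetics. Passing recovery tests on synthetic data
therefore demonstrates correctness of the pipeline (profile construction,
search, analytics), not adequacy of the model for any particular real
dataset.

## Problem sizes used in the shipped checks

Reference-density checks are exact-root computations (sub-second). The
recovery check searches the full 10⁶-hexad shipped grid. The
ensemble-vs-analytic comparison uses 2000 paths to `T = 200 h` at
`dt = 2×10⁻³`; mode-structure runs use 500 paths per configuration to
`T = 150 h`. These sizes put Monte-Carlo error comfortably inside the
stated tolerances (two-sample KS noise at n = 2000 is ≈ 0.03 at 95%).

## Known limitations

* Colored (Ornstein–Uhlenbeck) noise is out of scope; only white noise is
  treated.
* No time-dependent Fokker–Planck solver; transients come from Monte
  Carlo.
* No fitting of `(D, Q, λ)` to data, and no uncertainty quantification on
  the grid-search estimates (the protocol provides none).
* The series approximations are local to `K`; callers needing the true
  threshold should use the numeric roots, which is why both are always
  reported together.
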