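# Methods

## Model

The package simulates and analyzes a single population living in `n`
habitat patches. Patch abundances `X(t) = (X_1, ..., X_n)` follow the Itô
system

    dX_i = [ X_i (a_i − b_i(X_i)) + Σ_j D_ji X_j ] dt + X_i dE_i ,

with

* `a_i` — per-capita growth rate of patch `i` (1/time);
* `b_i` — per-capita intraspecific competition, locally Lipschitz with
  `b_i(0) = 0`. The workhorse choice is linear, `b_i(x) = κ_i x` (logistic
  self-limitation); any per-capita growth function `f_i` can be brought to
  this form via `a_i = f_i(0)`, `b_i(x) = f_i(0) − f_i(x)`;
* `D` — dispersal matrix: `D_ij ≥ 0` for `i ≠ j` is the per-capita
  movement rate from patch `i` to `j`, diagonal entries balance each row to
  zero. `D` is the generator of a Markov chain on patches and must be
  irreducible (every patch reachable from every patch), which we check as
  strong connectivity of the positive-rate digraph;
* `E = Γᵀ B` — environmental noise: `B` is a vector of `k` independent
  Brownian motions and `Γ` a `k×n` loading matrix with covariance
  `Σ = ΓᵀΓ`. `rank(Σ) < n` (singular values below 1e-10 of the largest)
  means fewer environmental factors than patches — *degenerate noise*; the
  fully synchronized case is a single Brownian motion driving every patch.

Dissipativity of the competition terms (the abundance-weighted mean of
`b_i(x_i) − a_i` eventually exceeding a positive constant) guarantees
non-explosion. For linear competition with positive slopes the constants
`(M_b, γ_b)` are produced analytically; for general `b_i` they are searched
on a grid, and since the condition quantifies over an unbounded set, a
failed search is reported as *inconclusive* rather than disproved.

## The stochastic growth rate

Writing `S = Σ_i X_i` and `Y = X/S`, the proportions decouple from the
total at low density: the competition-free proportion process `Ỹ` is an
autonomous diffusion on the simplex, with unique stationary law `ν*`, and

    r = ∫_Δ ( aᵀy − ½ yᵀΣy ) ν*(dy)

is the Lyapunov exponent of the linearized total: `ln 𝒮(t)/t → r` almost
surely. `r > 0` implies persistence (convergence to a unique invariant law
on positive abundances; the occupation time near the extinction boundary is
eventually negligible), `r < 0` implies extinction at exponential rate `r`
in every patch. The `r = 0` boundary is not covered by the theory and is
classified as *inconclusive*, as is any estimate whose 3-standard-error
band straddles zero.

### Estimators

* `single_patch` (n = 1): `r = a − σ²/2` exactly.
* `quadrature_2p` (n = 2, nonzero proportion diffusion): substituting
  `Y_2 = 1 − Y_1` gives a scalar diffusion on (0,1) with drift
  `μ(y) = d21 − (d12+d21) y + y(1−y)[(a1−a2) − (Σ11−Σ12) y + (Σ22−Σ12)(1−y)]`
  and squared volatility `s²(y) = y²(1−y)² c`, `c = Σ11 − 2Σ12 + Σ22`.
  The scale/speed construction `ρ ∝ s⁻² exp(∫ 2μ/s²)` integrates in closed
  form to

      log ρ(y) = p log y + q log(1−y) − (2/c)(d21/y + d12/(1−y)) + const,
      p = −2 + (2/c)(d21 − d12 + a1 − a2 + Σ22 − Σ12),
      q = −2 + (2/c)(d12 − d21 + a2 − a1 + Σ11 − Σ12),

  one formula covering independent, partially correlated, and rank-one
  (perfectly correlated, unequal volatility) noise. The boundary factors
  vanish faster than any power at 0 and 1 (entrance boundaries), so the
  normalization and the moments `m1, m2` are computed by adaptive
  quadrature directly on (0,1) at tolerance 1e-10, with the normalization
  constant carried in log space. Then

      r = a2 − Σ22/2 + (a1 − a2 + Σ22 − Σ12) m1 − (c/2) m2 .

  The `Σ22 − Σ12` in the `m1` coefficient matters: it reduces to the
  familiar `a1 − a2 + σ2²` only when `Σ12 = 0`, and using the diagonal-case
  coefficient under correlated noise is wrong (it fails the Monte-Carlo
  cross-check by many standard errors; the point-mass limit below and the
  simulated `ln S(T)/T` both confirm the general form).
* `closedform_equal_sigma` (equal volatilities, perfect correlation):
  `c = 0`, the proportion dynamics are a deterministic ODE whose unique
  equilibrium `y*` in [0,1] solves `(a1−a2)(1−y)y + d21 − (d12+d21)y = 0`;
  `ν*` is the point mass at `y*` and `r = a2 − σ²/2 + (a1 − a2) y*`
  (the quadratic is solved in closed form for symmetric dispersal, by
  bracketed root finding otherwise; the `a1 = a2` degeneration returns the
  balance `d21/(d12+d21)` analytically). `c` below 1e-12 of the largest
  covariance entry routes here, because the quadrature density is
  numerically singular in that limit.
* `mc_timeaverage` (any n): the time average of `f(Ỹ) = aᵀỸ − ½ỸᵀΣỸ`
  along simulated proportion paths, averaged over replicates advanced in
  lockstep with independent Brownian streams; the standard error is the
  replicate-mean spread over √replicates. Defaults T = 1000, burn-in 100,
  16 replicates, dt = 1e-3 — the study fixtures mix on O(1–10) time
  scales, so the burn-in removes the transient with two orders of margin.
  For degenerate noise with n > 2, uniqueness of `ν*` is conjectural, and
  the estimate is conditional on apparent ergodicity.
* `large_dispersal_approx` (symmetric dispersal α, synchronized equal
  noise): `r ≈ (a1+a2)/2 − σ²/2 + (a1−a2)²/(8α)`. Its true error is
  O(1/α³) (the next term of the square-root expansion), so tests assert
  the weaker 1/α² decay bound. Under perfect correlation `r` *decreases*
  with α — mixing reduces growth when growth rates differ (the reduction
  principle); coupling two synchronized sink patches can never produce
  persistence, unlike the independent-noise case.

## Numerical integration

The default integrator advances `(Y, ln S)` rather than `X`: the proportion
step is Euler–Maruyama followed by simplex projection (truncate negatives,
renormalize — an Euler step can exit the simplex by O(√dt), the exact
dynamics never does), and the total moves in log scale with the Itô
correction `−½YᵀΣY`, so positivity and overflow control are structural.
A direct Euler–Maruyama scheme on `X` with negative proposals clamped to
zero is kept as a cross-check; both schemes see identical Brownian
increments for the same seed, and their pathwise gap contracts as dt is
refined (about 4% at dt = 2.5e-5 over a horizon of 10 on the two-patch
reference fixture with patch variance 7 — at that noise level dt = 1e-3 is
far too coarse for pathwise scheme comparisons, though fine for the
ergodic averages the growth-rate estimators need). Degenerate noise needs
no special casing: `Γ` simply has fewer rows than patches. One root seed
drives everything through numpy `Generator` streams, and coupled
comparisons (schemes, dispersal multipliers, perturbations) share a
`NoisePath`.

## Diagnostics

* **Classification** — persistent / extinct / inconclusive from the sign of
  `r` against `max(tolerance, 3·se)`.
* **Occupation fraction** — fraction of grid times with `min_i X_i ≤ η`
  (left-endpoint rule), the empirical occupation measure of the
  near-extinction set; default η grid {0.001, 0.01, 0.1}.
* **Extinction slopes** — least-squares slopes of `ln X_i` on the final
  half of the horizon (the prediction is an asymptotic statement; early
  transients bias the fit). A single tail slope carries Brownian noise of
  std ≈ σ√(1.2/L) for window length L, so quantitative recovery of `r`
  averages slopes over replicate paths.
* **θ-perturbation** — one seeded random direction scaled so growth rates,
  off-diagonal dispersal and noise loading each move at most 0.99·θ in
  norm; dispersal rows are re-balanced through the diagonal so the
  perturbed `D` stays a valid generator, and a θ exceeding the smallest
  off-diagonal rate is rejected. Persistence of a clearly persistent model
  (r ≥ 0.2) is invariant under shrinking θ, and `|Δr|` shrinks with θ.
* **Synchronized manifold** — on the slice (equal volatility and
  competition, `2(d21 − d12) = a2 − a1`) the two patches driven by one
  Brownian motion synchronize: equal starts stay equal (verified to
  discretization exactness), the ratio `X1/X2` never crosses 1 and decays
  toward it, and both patches track the scalar logistic diffusion
  `dU = U(a1 − d12 + d21 − bU)dt + σU dB` on the same noise path, so the
  invariant law concentrates on the diagonal manifold instead of filling
  the positive quadrant.
* **Infinite-dispersal limit** — scaling `D → δD` collapses proportions
  onto the dominant left eigenvector of `D` (the stationary law of the
  patch chain); the tail-averaged deviation is monotone decreasing along
  δ ∈ {1, 10, 100}.
* **Density comparison** — L1 distance between the histogram of a long
  proportion run and the stationary density's bin masses (50 equal bins);
  an inverse-CDF sampler of the density itself calibrates the sampling
  noise floor (≈ 0.02 at 1e5 draws).

## Study conditions and problem sizes

The named fixtures are: the two-patch reference sweep (a = (3, 4),
patch variances 7, symmetric dispersal α, correlation ρ ∈ [0, 1] — ρ = 0
independent patches, ρ = 1 one shared Brownian motion), its degenerate
equal-volatility variant, the synchronized-manifold slice (a1 = a2 = 2,
α = β = 0.5, σ = 1, b = 1, r = 1.5), the scalar logistic benchmark
(a = 3, σ² = 7, r = −0.5), and an exchangeable n-patch model for symmetry
checks. Ergodic averages use T = 1000 (burn-in 100) with 16 replicates at
dt = 1e-3; the density comparison uses a single T = 2000 path; extinction
slopes average 12 paths of T = 500 at dt = 1e-2 (the log-scale update is
exact in the frozen-proportion regime of that fixture, so the coarser step
costs only transient bias). These horizons put Monte-Carlo error an order
of magnitude below the effects being measured.

## What the simulations do and do not show

The generator produces exactly the model class the theory covers:
log-linear environmental noise with constant covariance, constant
dispersal, memoryless (white-noise) environments and a single unstructured
population. Passing tests therefore validate the implementation and the
formulas under the model's own assumptions; they say nothing about
age/stage structure, environmental autocorrelation, demographic
stochasticity at small abundance, or density-dependent dispersal, none of
which are in the model. The polynomial rate of convergence to the
invariant law is not checked (only qualitative stationarity through the
density comparison), the `r = 0` boundary is deliberately unclassified,
and the general-n stationary density is not attempted — for n > 2 only the
Monte-Carlo route is available.

## Known limitations

* Euler–Maruyama is strong order 1/2; pathwise statements (scheme
  agreement, manifold identities) are checked at the dt where
  discretization error is below the assertion tolerance, not at the
  ergodic-average dt.
* The quadrature density becomes numerically stiff as `c → 0` (the
  point-mass threshold handles the exact limit but near-threshold specs
  inherit large exponents); moments remain accurate because the boundary
  factors dominate.
* State-dependent θ-perturbations are constructed and bound-checked but
  not simulatable; constant perturbations are, and are what the
  robustness checks use.
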