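# patchsde

Stochastic population dynamics in patchy environments: will a population
that disperses among heterogeneous habitat patches, competes with itself,
and experiences spatially correlated environmental fluctuations persist or
go extinct?

The package implements the density-dependent n-patch model

    dX_i = [ X_i (a_i − b_i(X_i)) + Σ_j D_ji X_j ] dt + X_i dE_i ,

where `X_i` is the abundance in patch `i`, `a_i` its per-capita growth
rate, `b_i` the intraspecific competition (typically `κ_i x`), `D` an
irreducible dispersal matrix (nonnegative off-diagonal rates, zero row
sums), and `E = Γᵀ B` environmental noise with covariance `Σ = ΓᵀΓ` —
possibly *degenerate* (rank(Σ) < n), e.g. one Brownian motion driving all
patches. The long-term fate is decided by the **stochastic growth rate**

    r = ∫_Δ ( aᵀy − ½ yᵀΣy ) ν*(dy) ,

the Lyapunov exponent of the linearized total population, where `ν*` is
the stationary law of the patch-proportion process on the simplex:
`r > 0` means persistence, `r < 0` means extinction at exponential rate
`r` in every patch. The package computes `r` by

* closed form for a single patch (`a − σ²/2`) and for the fully
  synchronized equal-volatility two-patch case (point-mass proportions),
* quadrature against the explicit stationary density of the two-patch
  proportion diffusion (independent, partially correlated, or rank-one
  noise — one scale/speed closed form covers all of them),
* Monte-Carlo time averaging of `aᵀỸ − ½ỸᵀΣỸ` along simulated
  proportion paths for any n,

and turns the supporting theory into executable diagnostics: persistence
classification, occupation measures near the extinction boundary,
extinction-rate recovery from path slopes, synchronized-manifold checks,
the infinite-dispersal limit, and robustness under θ-perturbations of all
model pieces. It is aimed at theoretical ecologists and applied
probabilists who want desk-scale numerical verification of
persistence/extinction criteria for metapopulation SDE models.

## Worked example

```python
import math
from patchsde import (TwoPatchSpec, stochastic_growth_rate,
                      classify_persistence, make_two_patch, r_mc_timeaverage)

# two patches: growth rates 3 and 4, equal patch variance 7, symmetric
# dispersal rate 1, perfectly synchronized environments (one Brownian motion)
spec = TwoPatchSpec(a1=3.0, a2=4.0, d12=1.0, d21=1.0,
                    sigma1=math.sqrt(7), sigma2=math.sqrt(7), rho=1.0)
res = stochastic_growth_rate(spec)
print(res.method, round(res.r, 6), round(res.diagnostics["ystar"], 6))
print(classify_persistence(res).verdict)

# cross-check by simulation
mc = r_mc_timeaverage(make_two_patch(spec), seed=1)
print(round(mc.r, 6), "+-", round(mc.se, 6))
```

prints

```
closedform_equal_sigma 0.118034 0.381966
persistent
0.118034 +- 0.0
```

Read: with one shared environment the proportion process settles at the
equilibrium `y* = (3 − √5)/2 ≈ 0.381966` (38% of the population in the
slower-growing patch), giving `r = (5 + √5)/2 − 7/2 ≈ 0.118 > 0` — the
population persists, but barely: each patch alone has `a − σ²/2` of −0.5
and 0.5, and under perfect correlation raising the dispersal rate *lowers*
`r` (the reduction principle), in sharp contrast to independent
environments where the same model at `rho=0` gives `r ≈ 1.319`. The MC
estimate has zero standard error here because the proportion dynamics are
deterministic in this degenerate case.

A command-line layer exposes the same machinery, e.g.

```sh
patchsde growth-rate --fixture two_patch_sweep --rho 1 --alpha 1
patchsde scan --fixture two_patch_sweep --alpha-grid 0.5:16:log --rho-grid 0,0.5,0.9,1 --out scan.csv
patchsde simulate --fixture two_patch_sweep --rho 0 --T 100 --out traj.csv
patchsde diagnose --trajectory traj.csv
```

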