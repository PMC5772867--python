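"""The stochastic growth rate r and two-patch stationary densities.

r is the Lyapunov exponent of the total population in the absence of
competition,

    r = int_Delta ( a^T y - 1/2 y^T Sigma y ) nu*(dy),

with nu* the stationary law of the proportion process Ytilde on the simplex.
Its sign separates persistence (r > 0) from extinction (r < 0); the r = 0
boundary is outside the theory and reported as inconclusive downstream.

For two patches the proportion of patch 1 is a scalar diffusion on (0, 1)

    dY = mu(y) dt + s(y) dB,
    mu(y) = d21 - (d12 + d21) y
            + y(1-y) [ (a1 - a2) - (S11 - S12) y + (S22 - S12)(1 - y) ],
    s(y)^2 = y^2 (1-y)^2 * c,     c = S11 - 2 S12 + S22,

(S = Sigma) whose stationary density follows from the scale/speed
construction rho(y) ~ s(y)^{-2} exp(int 2 mu / s^2). The integral has the
closed form

    log rho(y) = p log y + q log(1-y) - (2/c)(d21/y + d12/(1-y)) + const,
    p = -2 + (2/c)(d21 - d12 + a1 - a2 + S22 - S12),
    q = -2 + (2/c)(d12 - d21 + a2 - a1 + S11 - S12),

covering the independent-noise, partially correlated, and rank-one
(perfectly correlated, unequal volatility) cases alike; the boundary
factors exp(-2 d21/(c y)) and exp(-2 d12/(c (1-y))) vanish faster than any
power at 0 and 1 (entrance boundaries), so adaptive quadrature on (0, 1) is
well behaved. When c = 0 (equal volatility, perfect correlation) the
proportion dynamics are a deterministic ODE and nu* is a point mass at the
root y* of the drift; everything then reduces to closed forms.

In terms of the density moments m1, m2 of Y(inf),

    r = a2 - S22/2 + (a1 - a2 + S22 - S12) m1 - (c/2) m2,

which specializes to the familiar a2 - sigma2^2/2 + (a1 - a2 + sigma2^2) m1
- (sigma1^2 + sigma2^2)/2 m2 when Sigma is diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .model import ModelError, PatchModel, TwoPatchSpec, make_two_patch
from .sde import make_noise_path

__all__ = [
    "GrowthRateResult",
    "StationaryDensity2P",
    "stochastic_growth_rate",
    "r_single_patch",
    "r_mc_timeaverage",
    "stationary_density_2p",
    "r_quadrature_2p",
    "r_closedform_equal_sigma",
    "r_large_dispersal_approx",
    "equilibrium_proportion",
    "two_patch_sigma",
]

QUAD_TOL = 1e-10
POINT_MASS_RTOL = 1e-12  # c below this times max |Sigma| routes to the ODE branch
MC_T = 1000.0
MC_BURN_IN = 100.0
MC_REPLICATES = 16
MC_DT = 1e-3


@dataclass
class GrowthRateResult:
    """An estimate of r with its provenance.

    ``se`` is 0 for deterministic methods; ``method`` is one of
    mc_timeaverage, quadrature_2p, closedform_equal_sigma, single_patch,
    large_dispersal_approx.
    """

    r: float
    se: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ModelError("standard error must be nonnegative")


def two_patch_sigma(spec: TwoPatchSpec) -> tuple[float, float, float]:
    """Covariance entries (S11, S12, S22) of a two-patch spec."""
    return (
        spec.sigma1**2,
        spec.rho * spec.sigma1 * spec.sigma2,
        spec.sigma2**2,
    )


@dataclass
class StationaryDensity2P:
    """Stationary law of the patch-1 proportion for a two-patch model.

    ``branch`` is ``nondegenerate`` (full-rank noise), ``degenerate_unequal``
    (rank-one noise, nonzero proportion diffusion), or ``point_mass`` (the
    proportion ODE case). For the density branches the unnormalized log
    density is ``(beta_exp - alpha1) log y + (-beta_exp - alpha2) log(1-y)
    - (2/scale)(d21/y + d12/(1-y))``: beta_exp = 2(a1-a2+d21-d12)/scale is
    the drift-asymmetry exponent and alpha1/alpha2 the volatility exponents
    (2 sigma_i^2/scale when Sigma is diagonal).
    """

    branch: str
    spec: TwoPatchSpec
    alpha1: float = np.nan
    alpha2: float = np.nan
    beta_exp: float = np.nan
    scale: float = np.nan
    logC: float = np.nan
    m1: float = np.nan
    m2: float = np.nan
    ystar: float = np.nan

    @property
    def pow_y(self) -> float:
        return self.beta_exp - self.alpha1

    @property
    def pow_1my(self) -> float:
        return -self.beta_exp - self.alpha2

    def log_density_unnormalized(self, y) -> np.ndarray:
        if self.branch == "point_mass":
            raise ModelError("point-mass branch has no density on (0,1)")
        y = np.asarray(y, dtype=float)
        s = self.spec
        with np.errstate(divide="ignore"):
            return (
                self.pow_y * np.log(y)
                + self.pow_1my * np.log1p(-y)
                - (2.0 / self.scale) * (s.d21 / y + s.d12 / (1.0 - y))
            )

    def pdf(self, y) -> np.ndarray:
        return np.exp(self.logC + self.log_density_unnormalized(y))

    def cdf_grid(self, num: int = 4001) -> tuple[np.ndarray, np.ndarray]:
        """Dense grid and normalized CDF, for inverse-CDF sampling."""
        ys = np.linspace(1e-9, 1 - 1e-9, num)
        pdf = self.pdf(ys)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(ys))])
        return ys, cdf / cdf[-1]


def _drift_mu(spec: TwoPatchSpec, y):
    S11, S12, S22 = two_patch_sigma(spec)
    return (
        spec.d21
        - (spec.d12 + spec.d21) * y
        + y * (1 - y) * ((spec.a1 - spec.a2) - (S11 - S12) * y + (S22 - S12) * (1 - y))
    )


def equilibrium_proportion(spec: TwoPatchSpec) -> float:
    """Root y* in [0, 1] of the proportion ODE drift (zero-diffusion case).

    Solves (a1-a2)(1-y)y + d21 - (d12+d21)y = 0. When a1 = a2 the quadratic
    degenerates to the linear balance d21/(d12+d21); the symmetric-dispersal
    closed form (a1-a2-2*alpha+sqrt((a1-a2)^2+4*alpha^2))/(2(a1-a2)) is used
    when d12 = d21 = alpha.
    """
    a1, a2, al, be = spec.a1, spec.a2, spec.d12, spec.d21
    if al + be <= 0:
        raise ModelError("equilibrium needs some dispersal (d12 + d21 > 0)")
    da = a1 - a2
    if da == 0:
        return be / (al + be)
    if al == be:
        return (da - 2 * al + math.sqrt(da * da + 4 * al * al)) / (2 * da)
    f = lambda y: da * (1 - y) * y + be - (al + be) * y
    # f(0) = d21 >= 0, f(1) = -d12 <= 0; the root is bracketed in [0, 1]
    return float(brentq(f, 0.0, 1.0, xtol=1e-12, rtol=8.9e-16))


def stationary_density_2p(spec: TwoPatchSpec) -> StationaryDensity2P:
    """Construct the stationary density (or point mass) of the patch-1
    proportion for a two-patch spec."""
    S11, S12, S22 = two_patch_sigma(spec)
    c = S11 - 2 * S12 + S22
    if spec.d12 + spec.d21 <= 0 or spec.d12 < 0 or spec.d21 < 0:
        raise ModelError("density formulas require migration (d12 + d21 > 0)")
    smax = max(abs(S11), abs(S12), abs(S22), 1.0)
    if c < POINT_MASS_RTOL * smax:
        ystar = equilibrium_proportion(spec)
        return StationaryDensity2P(
            branch="point_mass", spec=spec, scale=c, ystar=ystar, m1=ystar,
            m2=ystar**2,
        )
    if spec.d12 == 0 or spec.d21 == 0:
        raise ModelError(
            "one-way dispersal: the proportion diffusion has an absorbing "
            "boundary and no interior stationary density"
        )
    rank1 = abs(S11 * S22 - S12 * S12) < 1e-12 * smax * smax
    branch = "degenerate_unequal" if rank1 else "nondegenerate"
    beta_exp = 2 * (spec.a1 - spec.a2 + spec.d21 - spec.d12) / c
    # pow_y = -2 + (2/c)(d21 - d12 + a1 - a2 + S22 - S12) = beta_exp - alpha1
    alpha1 = 2 * (S11 - S12) / c
    alpha2 = 2 * (S22 - S12) / c
    dens = StationaryDensity2P(
        branch=branch, spec=spec, alpha1=alpha1, alpha2=alpha2,
        beta_exp=beta_exp, scale=c,
    )
    # normalize in log space: shift by the max of log rho on a probe grid
    probe = np.linspace(1e-6, 1 - 1e-6, 2001)
    lr = dens.log_density_unnormalized(probe)
    shift = float(lr.max())
    f0 = lambda y: math.exp(
        float(dens.log_density_unnormalized(y)) - shift
    )
    Z, _ = quad(f0, 0.0, 1.0, epsabs=QUAD_TOL, epsrel=QUAD_TOL, limit=200)
    dens.logC = -(shift + math.log(Z))
    dens.m1, _ = quad(lambda y: y * f0(y) / Z, 0, 1, epsabs=QUAD_TOL, epsrel=QUAD_TOL, limit=200)
    dens.m2, _ = quad(lambda y: y * y * f0(y) / Z, 0, 1, epsabs=QUAD_TOL, epsrel=QUAD_TOL, limit=200)
    return dens


def _r_from_moments(spec: TwoPatchSpec, m1: float, m2: float) -> float:
    S11, S12, S22 = two_patch_sigma(spec)
    c = S11 - 2 * S12 + S22
    return spec.a2 - S22 / 2 + (spec.a1 - spec.a2 + S22 - S12) * m1 - (c / 2) * m2


def r_single_patch(a: float, sigma_sq: float) -> GrowthRateResult:
    """Single-patch growth rate a - sigma^2/2 (geometric Brownian motion)."""
    if sigma_sq < 0:
        raise ModelError("sigma_sq must be nonnegative")
    return GrowthRateResult(r=a - sigma_sq / 2, se=0.0, method="single_patch")


def r_quadrature_2p(
    spec: TwoPatchSpec, density: StationaryDensity2P | None = None
) -> GrowthRateResult:
    """r from the explicit stationary density via its first two moments."""
    if density is None:
        density = stationary_density_2p(spec)
    if density.branch == "point_mass":
        raise ModelError(
            "zero proportion diffusion: use r_closedform_equal_sigma"
        )
    r = _r_from_moments(spec, density.m1, density.m2)
    return GrowthRateResult(
        r=r, se=0.0, method="quadrature_2p",
        diagnostics={"branch": density.branch, "m1": density.m1, "m2": density.m2,
                     "quad_tol": QUAD_TOL},
    )


def r_closedform_equal_sigma(spec: TwoPatchSpec) -> GrowthRateResult:
    """r for equal volatilities under perfect correlation.

    The proportion process is then a deterministic ODE with a unique stable
    equilibrium y* in [0, 1], the stationary law is the point mass there,
    and r = a2 - sigma^2/2 + (a1 - a2) y*. With symmetric dispersal alpha
    this is (a1 + a2 - 2 alpha + sqrt((a1-a2)^2 + 4 alpha^2))/2 - sigma^2/2.
    """
    S11, S12, S22 = two_patch_sigma(spec)
    c = S11 - 2 * S12 + S22
    if c >= POINT_MASS_RTOL * max(abs(S11), abs(S22), 1.0):
        raise ModelError(
            "nonzero proportion diffusion: use r_quadrature_2p instead"
        )
    ystar = equilibrium_proportion(spec)
    r = _r_from_moments(spec, ystar, ystar**2)
    return GrowthRateResult(
        r=r, se=0.0, method="closedform_equal_sigma",
        diagnostics={"ystar": ystar},
    )


def r_large_dispersal_approx(spec: TwoPatchSpec) -> GrowthRateResult:
    """Large-dispersal expansion for the symmetric fully correlated case:
    r ~ (a1+a2)/2 - sigma^2/2 + (a1-a2)^2/(8 alpha), converging to the
    dispersal-averaged single-patch rate as alpha grows."""
    if spec.d12 != spec.d21:
        raise ModelError("approximation assumes symmetric dispersal d12 = d21")
    if spec.d12 <= 0:
        raise ModelError("approximation needs alpha > 0")
    sigma_sq = spec.sigma1**2
    al = spec.d12
    r = (spec.a1 + spec.a2) / 2 - sigma_sq / 2 + (spec.a1 - spec.a2) ** 2 / (8 * al)
    return GrowthRateResult(r=r, se=0.0, method="large_dispersal_approx")


def r_mc_timeaverage(
    model: PatchModel,
    T: float = MC_T,
    burn_in: float = MC_BURN_IN,
    replicates: int = MC_REPLICATES,
    dt: float = MC_DT,
    seed: int | None = None,
) -> GrowthRateResult:
    """Monte-Carlo r: time average of f(Ytilde) = a^T y - 1/2 y^T Sigma y
    along the competition-free simplex process, averaged over replicates.

    The replicate ensemble is advanced in lockstep (vectorized across
    replicates, independent Brownian streams); the standard error is the
    replicate-mean spread / sqrt(replicates).
    """
    if replicates < 2:
        raise ModelError("need at least 2 replicates to form a standard error")
    if not T > burn_in >= 0:
        raise ModelError("need T > burn_in >= 0")
    a, Sigma, G, D = model.a, model.Sigma, model.Gamma, model.D
    n, k = model.n, model.Gamma.shape[0]
    K = int(round(T / dt))
    kburn = int(round(burn_in / dt))
    rng = np.random.default_rng(seed)
    y = np.full((replicates, n), 1.0 / n)
    acc = np.zeros(replicates)
    count = 0
    sq = math.sqrt(dt)
    # blocks of pre-drawn noise keep memory flat on long horizons
    block = 20000
    done = 0
    while done < K:
        m = min(block, K - done)
        dBs = rng.standard_normal((m, replicates, k)) * sq
        for j in range(m):
            Sy = y @ Sigma
            if done + j >= kburn:
                f = y @ a - 0.5 * np.einsum("ri,ri->r", y, Sy)
                acc += f
                count += 1
            gdB = dBs[j] @ G  # (replicates, n) increments of E
            arg = (a - Sy) * dt + gdB
            y = y + y * arg - y * np.einsum("ri,ri->r", y, arg)[:, None] + (y @ D) * dt
            np.clip(y, 0.0, None, out=y)
            y /= y.sum(axis=1, keepdims=True)
        done += m
    means = acc / count
    r = float(means.mean())
    se = float(means.std(ddof=1) / math.sqrt(replicates))
    return GrowthRateResult(
        r=r, se=se, method="mc_timeaverage",
        diagnostics={"T": T, "burn_in": burn_in, "replicates": replicates, "dt": dt},
    )


def _spec_from_model(model: PatchModel) -> TwoPatchSpec:
    if model.n != 2:
        raise ModelError("two-patch spec requires n = 2")
    S = model.Sigma
    s1, s2 = math.sqrt(S[0, 0]), math.sqrt(S[1, 1])
    rho = S[0, 1] / (s1 * s2) if s1 > 0 and s2 > 0 else 0.0
    kappa = model.kappa if model.kappa is not None else np.array([1.0, 1.0])
    return TwoPatchSpec(
        a1=float(model.a[0]), a2=float(model.a[1]),
        comp1=float(kappa[0]), comp2=float(kappa[1]),
        d12=float(model.D[0, 1]), d21=float(model.D[1, 0]),
        sigma1=s1, sigma2=s2, rho=float(np.clip(rho, -1, 1)),
    )


def stochastic_growth_rate(
    model: PatchModel | TwoPatchSpec,
    method: str = "auto",
    seed: int | None = None,
    **mc_kwargs,
) -> GrowthRateResult:
    """Compute r, dispatching on the model structure.

    auto: n=1 -> single_patch; n=2 with zero proportion diffusion ->
    closedform_equal_sigma; n=2 otherwise -> quadrature_2p; n>2 ->
    mc_timeaverage. An explicit method overrides but raises if inapplicable.
    """
    spec = model if isinstance(model, TwoPatchSpec) else None
    if spec is not None:
        model = make_two_patch(spec)
    n = model.n
    if method == "auto":
        if n == 1:
            method = "single_patch"
        elif n == 2:
            if spec is None:
                spec = _spec_from_model(model)
            S11, S12, S22 = two_patch_sigma(spec)
            c = S11 - 2 * S12 + S22
            method = (
                "closedform_equal_sigma"
                if c < POINT_MASS_RTOL * max(abs(S11), abs(S22), 1.0)
                else "quadrature_2p"
            )
        else:
            method = "mc_timeaverage"
    if method == "single_patch":
        if n != 1:
            raise ModelError(
                "single_patch applies only to n=1; valid here: "
                + ("quadrature_2p, closedform_equal_sigma, mc_timeaverage" if n == 2 else "mc_timeaverage")
            )
        return r_single_patch(float(model.a[0]), float(model.Sigma[0, 0]))
    if method == "quadrature_2p":
        if n != 2:
            raise ModelError("quadrature_2p applies only to n=2; valid here: mc_timeaverage")
        return r_quadrature_2p(spec or _spec_from_model(model))
    if method == "closedform_equal_sigma":
        if n != 2:
            raise ModelError("closedform_equal_sigma applies only to n=2; valid here: mc_timeaverage")
        return r_closedform_equal_sigma(spec or _spec_from_model(model))
    if method == "mc_timeaverage":
        return r_mc_timeaverage(model, seed=seed, **mc_kwargs)
    if method == "large_dispersal_approx":
        return r_large_dispersal_approx(spec or _spec_from_model(model))
    raise ModelError(f"unknown method {method!r}")
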