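"""Executable checks of the persistence/extinction theory.

The sign of the stochastic growth rate r decides the fate of the
population: r > 0 gives convergence to a unique invariant law supported on
positive abundances (stochastic persistence: the occupation time near the
extinction boundary is eventually negligible), r < 0 gives almost-sure
exponential extinction at rate r in every patch. This module turns those
statements, plus the synchronized-patches case, the infinite-dispersal
limit, and robustness under model perturbation, into measurable
diagnostics on simulated paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import ModelError, PatchModel, validate_dispersal
from .sde import NoisePath, Trajectory, make_noise_path, simulate_X
from .growth import GrowthRateResult, StationaryDensity2P

__all__ = [
    "ClassificationResult",
    "OccupationStats",
    "PerturbedModel",
    "classify_persistence",
    "occupation_fraction",
    "extinction_slopes",
    "make_theta_perturbation",
    "synchronized_patches_diagnostics",
    "synchronized_slice_check",
    "infinite_dispersal_check",
    "dominant_eigenweights",
    "empirical_density_compare",
]


@dataclass
class ClassificationResult:
    verdict: str  # persistent | extinct | inconclusive
    r_used: GrowthRateResult
    tolerance: float


@dataclass
class OccupationStats:
    """Fraction of sampled times some patch abundance is at or below eta."""

    eta: float
    fraction: float
    t_window: tuple[float, float]


@dataclass
class PerturbedModel:
    """A model whose pieces deviate from a base model by at most theta."""

    base: PatchModel
    theta: float
    model: PatchModel | None  # constant-mode perturbation as a plain model
    mode: str
    sup_deviation: dict = field(default_factory=dict)


def classify_persistence(
    r_result: GrowthRateResult, tolerance: float = 1e-6
) -> ClassificationResult:
    """Persistent if r clears both the tolerance band and 3 standard errors
    above 0; extinct symmetrically below; the r = 0 boundary (within the
    band) is inconclusive because the theory does not cover it."""
    band = max(tolerance, 3 * r_result.se)
    if r_result.r > band:
        verdict = "persistent"
    elif r_result.r < -band:
        verdict = "extinct"
    else:
        verdict = "inconclusive"
    return ClassificationResult(verdict=verdict, r_used=r_result, tolerance=tolerance)


def occupation_fraction(traj: Trajectory, eta: float) -> OccupationStats:
    """Time fraction with min_i X_i <= eta (left-endpoint rule on the grid),
    the empirical occupation measure of the near-extinction set."""
    if eta <= 0:
        raise ModelError("eta must be positive")
    if traj.times.size == 0:
        raise ModelError("empty trajectory")
    mins = traj.X[:-1].min(axis=1)  # left endpoints of the K steps
    frac = float(np.mean(mins <= eta)) if mins.size else 0.0
    return OccupationStats(
        eta=eta, fraction=frac, t_window=(float(traj.times[0]), float(traj.times[-1]))
    )


def extinction_slopes(traj: Trajectory, window_frac: float = 0.5):
    """Least-squares slopes of ln X_i over the final window of the grid.

    In an extinct regime every patch shares the slope r, so the spread of
    the fitted slopes measures agreement with that prediction. Early
    transients bias the fit, hence only the tail window is used.
    """
    K = traj.times.size
    k0 = int(K * (1 - window_frac))
    t = traj.times[k0:]
    Xw = traj.X[k0:]
    if np.any(Xw <= 0):
        raise ModelError(
            "zero abundance in fit window: log-slope undefined; shorten the window"
        )
    slopes = np.polyfit(t, np.log(Xw), 1)[0]
    return np.atleast_1d(slopes), float(np.ptp(np.atleast_1d(slopes)))


def make_theta_perturbation(
    base: PatchModel,
    theta: float,
    mode: str = "constant",
    seed: int | None = None,
) -> PerturbedModel:
    """Build a theta-perturbation of a model.

    constant mode draws one random direction (uniform in [-1, 1] per entry,
    scaled so each piece moves by at most 0.99 * theta in sup norm) for the
    growth rates, the off-diagonal dispersal rates, and the noise loading;
    dispersal rows are re-balanced through the diagonal so the perturbed D
    stays a dispersal matrix. state_dependent mode attaches smooth bounded
    bump multipliers instead (validated on a grid, not simulatable).
    """
    if theta < 0:
        raise ModelError("theta must be nonnegative")
    rng = np.random.default_rng(seed)
    amp = 0.99 * theta
    off = base.D.copy()
    np.fill_diagonal(off, 0.0)
    pos = off[off > 0]
    if theta > 0 and pos.size and amp >= pos.min():
        raise ModelError(
            f"theta={theta} would break the sign of the smallest dispersal rate "
            f"{pos.min():g}; use a smaller theta"
        )
    da = rng.uniform(-1, 1, size=base.n)
    dD = rng.uniform(-1, 1, size=base.D.shape)
    dG = rng.uniform(-1, 1, size=base.Gamma.shape)
    if mode == "constant":
        a_hat = base.a + amp * da
        D_hat = base.D.copy()
        mask = ~np.eye(base.n, dtype=bool)
        D_hat[mask] += amp * dD[mask] / base.n  # keep ||D - D_hat|| <= theta
        np.fill_diagonal(D_hat, 0.0)
        np.fill_diagonal(D_hat, -D_hat.sum(axis=1))
        G_hat = base.Gamma + amp * dG / math.sqrt(base.Gamma.size)
        pert = PatchModel(
            n=base.n, a=a_hat, b=list(base.b), D=D_hat, Gamma=G_hat,
            competition_kind=base.competition_kind,
            kappa=None if base.kappa is None else base.kappa.copy(),
        )
        rep = validate_dispersal(D_hat)
        if not rep.passed:
            raise ModelError(f"perturbed dispersal invalid: {rep.detail}")
        dev = {
            "a": float(np.max(np.abs(a_hat - base.a))),
            "D": float(np.linalg.norm(D_hat - base.D, 2)),
            "Gamma": float(np.linalg.norm(G_hat - base.Gamma, 2)),
        }
        return PerturbedModel(base=base, theta=theta, model=pert, mode=mode,
                              sup_deviation=dev)
    if mode == "state_dependent":
        # bounded smooth bumps: piece(x) = base + amp * u * 1/(1 + |x|^2)
        bump = lambda x: 1.0 / (1.0 + float(np.dot(x, x)))
        grid = [np.full(base.n, v) for v in (0.0, 0.5, 1.0, 5.0, 50.0)]
        dev = {
            "a": max(abs(amp * da).max() * bump(x) for x in grid),
            "Gamma": max((abs(amp * dG).max()) * bump(x) for x in grid),
        }
        return PerturbedModel(base=base, theta=theta, model=None, mode=mode,
                              sup_deviation=dev)
    raise ModelError(f"unknown perturbation mode {mode!r}")


# ---------------------------------------------------------------------------
# synchronized two-patch case
# ---------------------------------------------------------------------------

def synchronized_slice_check(a1, a2, d12, d21, sigma, b) -> None:
    """Verify the parameter identities of the synchronized slice:
    equal volatility and competition, with 2(d21 - d12) = a2 - a1; on it
    d21 + (a1 - a2 - d12 + d21) - d12 = 0 holds (the degeneracy that breaks
    the absolutely-continuous-invariant-measure theorem)."""
    if abs(2 * (d21 - d12) - (a2 - a1)) > 1e-10:
        raise ModelError(
            f"off slice: 2(d21 - d12) = {2*(d21-d12):g} != a2 - a1 = {a2-a1:g}"
        )
    ident = d21 + 1.0 * (a1 - a2 - d12 + d21) - d12 * 1.0**2  # b2/b1 = 1
    if abs(ident) > 1e-10:
        raise ModelError(f"slice identity violated: {ident:g} != 0")


def synchronized_patches_diagnostics(
    a1: float,
    a2: float,
    d12: float,
    d21: float,
    sigma: float,
    b: float,
    x0,
    T: float = 200.0,
    dt: float = 1e-3,
    seed: int | None = None,
) -> dict:
    """Co-simulate the synchronized two-patch system and its reference
    logistic diffusion U on one Brownian path.

    On the slice (equal sigma and competition, 2(d21-d12) = a2-a1) equal
    starts force X1 = X2 = U forever; unequal starts keep the sign of
    Z - 1 = X1/X2 - 1, which decays, and both X_i/U -> 1, so the invariant
    law concentrates on the diagonal manifold x1 = x2.
    """
    synchronized_slice_check(a1, a2, d12, d21, sigma, b)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (2,) or np.any(x0 <= 0):
        raise ModelError("x0 must be two positive abundances")
    rng = np.random.default_rng(seed)
    K = int(round(T / dt))
    sq = math.sqrt(dt)
    x1, x2 = float(x0[0]), float(x0[1])
    u = float(x0[1])
    au = a1 - d12 + d21  # drift rate of U
    z0 = x1 / x2
    zmin, zmax = z0, z0
    maxdiff = 0.0
    for _ in range(K):
        dB = rng.standard_normal() * sq
        n1 = x1 + (x1 * (a1 - b * x1) - d12 * x1 + d21 * x2) * dt + sigma * x1 * dB
        n2 = x2 + (x2 * (a2 - b * x2) + d12 * x1 - d21 * x2) * dt + sigma * x2 * dB
        u = u + u * (au - b * u) * dt + sigma * u * dB
        x1, x2 = max(n1, 0.0), max(n2, 0.0)
        u = max(u, 0.0)
        maxdiff = max(maxdiff, abs(x1 - x2))
        if x2 > 0:
            z = x1 / x2
            zmin, zmax = min(zmin, z), max(zmax, z)
    r = a1 - d12 + d21 - sigma**2 / 2
    return {
        "r": r,
        "max_abs_diff": maxdiff,
        "Z0": z0,
        "Z_final": x1 / x2 if x2 > 0 else math.inf,
        "Z_min": zmin,
        "Z_max": zmax,
        "ratio1": x1 / u if u > 0 else math.inf,
        "ratio2": x2 / u if u > 0 else math.inf,
    }


# ---------------------------------------------------------------------------
# infinite-dispersal limit
# ---------------------------------------------------------------------------

def dominant_eigenweights(D: np.ndarray) -> np.ndarray:
    """Left null vector of the dispersal generator, normalized to sum 1.

    This is the stationary distribution of the patch-movement Markov chain;
    as dispersal is scaled up the patch proportions collapse onto it.
    """
    rep = validate_dispersal(D)
    if not rep.passed:
        raise ModelError(f"reducible dispersal: {rep.detail}")
    D = np.asarray(D, dtype=float)
    w, v = np.linalg.eig(D.T)
    i = int(np.argmin(np.abs(w)))
    alpha = np.real(v[:, i])
    alpha = alpha / alpha.sum()
    if np.any(alpha <= 0):
        raise ModelError("eigenweights not entrywise positive")
    return alpha


def infinite_dispersal_check(
    base: PatchModel,
    delta_grid=(1.0, 10.0, 100.0),
    T: float = 200.0,
    dt: float = 1e-3,
    burn_in: float = 50.0,
    seed: int | None = None,
    x0=None,
) -> dict:
    """Tail-averaged deviation of patch proportions from the eigenweights
    for each dispersal multiplier delta (same Brownian path across deltas).
    The deviations should shrink as delta grows."""
    alpha = dominant_eigenweights(base.D)
    if x0 is None:
        x0 = np.ones(base.n)
    noise = make_noise_path(base.Gamma.shape[0], T, dt, seed)
    k0 = int(round(burn_in / dt))
    devs = []
    for delta in delta_grid:
        m = base.with_dispersal(delta * base.D)
        traj = simulate_X(m, x0, T, dt, noise=noise)
        dev = np.abs(traj.Y[k0:] - alpha).max(axis=1).mean()
        devs.append(float(dev))
    return {"delta_grid": list(delta_grid), "eigenweights": alpha,
            "deviations": devs,
            "monotone_decreasing": all(b < a for a, b in zip(devs, devs[1:]))}


# ---------------------------------------------------------------------------
# empirical density comparison
# ---------------------------------------------------------------------------

def empirical_density_compare(
    samples: np.ndarray,
    density: StationaryDensity2P,
    bins: int = 50,
) -> float:
    """L1 distance between the histogram of patch-1 proportion samples and
    the stationary density's bin masses on equal-width bins of [0, 1].

    For the point-mass branch the comparison degenerates; use the distance
    of the empirical mean from y* instead (raised as an error here).
    """
    if density.branch == "point_mass":
        raise ModelError(
            "point-mass branch: compare the empirical mean against ystar"
        )
    samples = np.asarray(samples, dtype=float).ravel()
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(samples, bins=edges)
    p_hat = hist / hist.sum()
    ys, cdf = density.cdf_grid(8 * bins + 1)
    cdf_at = np.interp(edges, ys, cdf, left=0.0, right=1.0)
    p = np.diff(cdf_at)
    return float(np.abs(p_hat - p).sum())
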