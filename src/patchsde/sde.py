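"""Seeded Euler--Maruyama integration of the patch SDE and its reductions.

Four coupled views of the same dynamics are integrated here:

* the abundance system X(t) itself;
* the (Y, ln S) decomposition into patch proportions Y = X/S and the total
  S = sum_i X_i, advanced in log scale so positivity of S is structural;
* the competition-free simplex process Ytilde, whose stationary law defines
  the stochastic growth rate r;
* the linearized system (competition set to zero), with ln of its total
  accumulated alongside to avoid overflow on long horizons.

One root seed drives everything through numpy Generator streams; coupled
comparisons (two schemes, or a model and its perturbation) can share a
Brownian path by passing the same ``NoisePath``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelError, PatchModel

__all__ = [
    "Trajectory",
    "SimplexTrajectory",
    "NoisePath",
    "make_noise_path",
    "simulate_X",
    "simulate_YS",
    "simulate_Ytilde",
    "simulate_linearized",
    "trajectory_to_csv",
    "trajectory_from_csv",
]

DEFAULT_DT = 1e-3
SIMPLEX_TOL = 1e-9


@dataclass
class NoisePath:
    """Brownian increments Delta B on a uniform grid (K steps, k motions)."""

    times: np.ndarray
    increments: np.ndarray  # K x k
    seed: int | None = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class Trajectory:
    """Sample path of abundances with the derived total and proportions."""

    times: np.ndarray
    X: np.ndarray  # (K+1) x n
    seed: int | None = None
    scheme: str = "ys_transform"

    @property
    def S(self) -> np.ndarray:
        return self.X.sum(axis=1)

    @property
    def Y(self) -> np.ndarray:
        S = self.S
        with np.errstate(divide="ignore", invalid="ignore"):
            Y = np.where(S[:, None] > 0, self.X / np.where(S == 0, 1.0, S)[:, None], 0.0)
        return Y


@dataclass
class SimplexTrajectory:
    """Path of the proportion process on the simplex."""

    times: np.ndarray
    Ytilde: np.ndarray  # (K+1) x n, rows on the simplex
    seed: int | None = None


def _grid(T: float, dt: float) -> np.ndarray:
    if dt <= 0 or T < dt:
        raise ModelError(f"need 0 < dt <= T, got dt={dt}, T={T}")
    K = int(round(T / dt))
    return np.linspace(0.0, K * dt, K + 1)


def make_noise_path(k: int, T: float, dt: float, seed: int | None) -> NoisePath:
    """Sample K x k standard Brownian increments with std sqrt(dt)."""
    times = _grid(T, dt)
    K = times.size - 1
    rng = np.random.default_rng(seed)
    dB = rng.standard_normal((K, k)) * np.sqrt(dt)
    return NoisePath(times=times, increments=dB, seed=seed)


def _project_simplex(y: np.ndarray) -> np.ndarray:
    """Truncate negatives to zero and renormalize rows to unit sum."""
    y = np.clip(y, 0.0, None)
    s = y.sum(axis=-1, keepdims=True)
    s = np.where(s == 0, 1.0, s)
    return y / s


def _check_simplex(y0: np.ndarray) -> np.ndarray:
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    if np.any(y0 < -SIMPLEX_TOL) or abs(y0.sum() - 1.0) > SIMPLEX_TOL:
        raise ModelError(f"initial point {y0} is not on the simplex")
    return np.clip(y0, 0.0, None) / y0.sum()


def _ys_core(
    model: PatchModel,
    y0: np.ndarray,
    lns0: float,
    noise: NoisePath,
    competition: bool,
    store: bool = True,
):
    """Shared (Y, ln S) integrator; ``competition=False`` gives the
    linearized total and the boundary simplex process in one pass.

    Works on a batch: ``y0`` may be (m, n) for m coupled replicates sharing
    nothing but the code path (each replicate uses its own noise column
    block is NOT supported here; batching is done by the callers that own
    independent noise paths).
    """
    a, Sigma, D, G = model.a, model.Sigma, model.D, model.Gamma
    Dt = D.T
    y = y0.copy()
    lns = lnsum = float(lns0)
    times = noise.times
    dt = noise.dt
    K = times.size - 1
    Ys = np.empty((K + 1, model.n)) if store else None
    lnS = np.empty(K + 1)
    if store:
        Ys[0] = y
    lnS[0] = lns
    dBs = noise.increments
    linear = model.competition_kind == "linear"
    kappa = model.kappa
    for k in range(K):
        dB = dBs[k]
        Sy = Sigma @ y
        drift = a - Sy
        if competition:
            x = np.exp(lns) * y
            bx = kappa * x if linear else model.b_vec(x)
            drift = drift - bx
        else:
            bx = 0.0
        gdB = G.T @ dB  # dE
        ydotE = float(y @ gdB)
        ySy = float(y @ Sy)
        # d ln S = ((a - b)^T y - 1/2 y^T Sigma y) dt + y^T Gamma^T dB
        fy = float((a - bx) @ y) if competition else float(a @ y)
        lns = lns + (fy - 0.5 * ySy) * dt + ydotE
        # dY = (diag(y) - y y^T)(Gamma^T dB + (a - Sigma y - b) dt) + D^T y dt
        P_arg_dt = drift * dt + gdB
        y = y + y * P_arg_dt - y * float(y @ P_arg_dt) + (Dt @ y) * dt
        y = np.clip(y, 0.0, None)
        tot = y.sum()
        y = y / (tot if tot > 0 else 1.0)
        if store:
            Ys[k + 1] = y
        lnS[k + 1] = lns
    return Ys, lnS, y, lns


def simulate_YS(
    model: PatchModel,
    y0,
    s0: float,
    T: float,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    noise: NoisePath | None = None,
):
    """Integrate the (Y, ln S) system; returns (SimplexTrajectory, S series).

    Euler--Maruyama on Y with simplex projection after every step (truncate
    negatives, renormalize), and an Ito-corrected log-scale update for the
    total, so S stays positive by construction.
    """
    if s0 <= 0:
        raise ModelError("s0 must be positive")
    y0 = _check_simplex(y0)
    if noise is None:
        noise = make_noise_path(model.Gamma.shape[0], T, dt, seed)
    Ys, lnS, _, _ = _ys_core(model, y0, np.log(s0), noise, competition=True)
    return SimplexTrajectory(noise.times, Ys, seed=seed), np.exp(lnS)


def simulate_Ytilde(
    model: PatchModel,
    y0,
    T: float,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    noise: NoisePath | None = None,
) -> SimplexTrajectory:
    """Integrate the competition-free simplex process Ytilde.

    In the two-patch equal-volatility fully correlated case the diffusion
    term cancels identically and the scheme reduces to the deterministic
    proportion ODE.
    """
    y0 = _check_simplex(y0)
    if noise is None:
        noise = make_noise_path(model.Gamma.shape[0], T, dt, seed)
    Ys, _, _, _ = _ys_core(model, y0, 0.0, noise, competition=False)
    return SimplexTrajectory(noise.times, Ys, seed=seed)


def simulate_linearized(
    model: PatchModel,
    x0,
    T: float,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    noise: NoisePath | None = None,
):
    """Integrate the linearized (competition-free) abundances.

    Returns ``(Trajectory, lnS)`` where lnS is the log of the linearized
    total, accumulated alongside the proportions so long horizons cannot
    overflow; the stored abundances are Y * exp(lnS) (clipped at overflow).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x0 < 0) or x0.sum() <= 0:
        raise ModelError("x0 must be nonnegative with positive total")
    if noise is None:
        noise = make_noise_path(model.Gamma.shape[0], T, dt, seed)
    s0 = x0.sum()
    Ys, lnS, _, _ = _ys_core(model, x0 / s0, np.log(s0), noise, competition=False)
    with np.errstate(over="ignore"):
        X = Ys * np.exp(lnS)[:, None]
    return Trajectory(noise.times, X, seed=seed, scheme="ys_transform"), lnS


def simulate_X(
    model: PatchModel,
    x0,
    T: float,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    scheme: str = "ys_transform",
    noise: NoisePath | None = None,
) -> Trajectory:
    """Integrate the abundance SDE.

    ``ys_transform`` (default) integrates (Y, ln S) and maps back
    X = Y * S, so abundances are nonnegative by construction;
    ``em_clamped`` is direct Euler--Maruyama on X with negative proposals
    clamped to zero, retained as a cross-check. The same seed produces the
    same Brownian increments under both schemes.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (model.n,):
        raise ModelError(f"x0 must have shape ({model.n},)")
    if np.any(x0 < 0):
        raise ModelError("x0 must be nonnegative")
    if noise is None:
        noise = make_noise_path(model.Gamma.shape[0], T, dt, seed)
    if x0.sum() == 0:
        X = np.zeros((noise.times.size, model.n))
        return Trajectory(noise.times, X, seed=seed, scheme=scheme)
    if scheme == "ys_transform":
        s0 = x0.sum()
        Ys, lnS, _, _ = _ys_core(model, x0 / s0, np.log(s0), noise, competition=True)
        X = Ys * np.exp(lnS)[:, None]
        return Trajectory(noise.times, X, seed=seed, scheme=scheme)
    if scheme == "em_clamped":
        a, D, G = model.a, model.D, model.Gamma
        Dt = D.T
        dt_ = noise.dt
        K = noise.times.size - 1
        X = np.empty((K + 1, model.n))
        x = x0.copy()
        X[0] = x
        for k in range(K):
            bx = model.b_vec(x)
            drift = x * (a - bx) + Dt @ x
            x = x + drift * dt_ + x * (G.T @ noise.increments[k])
            x = np.clip(x, 0.0, None)
            X[k + 1] = x
        return Trajectory(noise.times, X, seed=seed, scheme=scheme)
    raise ModelError(f"unknown scheme {scheme!r}; use 'ys_transform' or 'em_clamped'")


# ---------------------------------------------------------------------------
# CSV serialization (t, X1..Xn, S, Y1..Yn)
# ---------------------------------------------------------------------------

def trajectory_to_csv(traj: Trajectory, path) -> None:
    n = traj.X.shape[1]
    cols = {"t": traj.times}
    for i in range(n):
        cols[f"X{i+1}"] = traj.X[:, i]
    cols["S"] = traj.S
    Y = traj.Y
    for i in range(n):
        cols[f"Y{i+1}"] = Y[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def trajectory_from_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    xcols = [c for c in df.columns if c.startswith("X")]
    return Trajectory(df["t"].to_numpy(), df[xcols].to_numpy())
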