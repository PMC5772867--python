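"""Model objects for the n-patch stochastic population system.

The state is a vector of patch abundances X(t) = (X_1, ..., X_n) driven by

    dX_i = [ X_i (a_i - b_i(X_i)) + sum_j D_ji X_j ] dt + X_i dE_i,

where a_i is the per-capita growth rate of patch i, b_i is the per-capita
intraspecific competition (b_i(0) = 0), D is a dispersal matrix (nonnegative
off-diagonal rates, zero row sums), and E = Gamma^T B couples the patches to
k independent Brownian motions through a loading matrix Gamma with
Gamma^T Gamma = Sigma. Rank(Sigma) < n means the environmental noise is
degenerate (fewer sources of randomness than patches); the fully correlated
two-patch case is a single Brownian motion driving both patches.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "PatchModel",
    "TwoPatchSpec",
    "AssumptionReport",
    "ModelError",
    "validate_dispersal",
    "build_noise",
    "from_growth_functions",
    "check_competition",
    "make_two_patch",
    "model_to_json",
    "model_from_json",
]

ROW_SUM_TOL = 1e-12
RANK_RTOL = 1e-10  # singular values below RANK_RTOL * s_max count as zero


class ModelError(ValueError):
    """Structural or parameter error in a model specification."""


@dataclass
class AssumptionReport:
    """Outcome of a numeric admissibility check.

    ``assumption_id`` is one of ``competition_2_2`` (dissipativity of the
    competition terms), ``irreducible_2_2`` (dispersal irreducibility) or
    ``nondegenerate_2_3`` (full-rank noise covariance). ``M_b``/``gamma_b``
    are the dissipativity constants when the competition check finds them.
    """

    assumption_id: str
    passed: bool
    detail: str = ""
    M_b: float | None = None
    gamma_b: float | None = None


@dataclass
class PatchModel:
    """Full parameterization of the n-patch SDE."""

    n: int
    a: np.ndarray
    b: list[Callable[[float], float]]
    D: np.ndarray
    Gamma: np.ndarray
    Sigma: np.ndarray = field(default=None)  # type: ignore[assignment]
    degenerate_flag: bool = False
    # metadata for serialization: ("linear", kappa) or ("callable", None)
    competition_kind: str = "callable"
    kappa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.D = np.asarray(self.D, dtype=float)
        self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        if self.Sigma is None:
            self.Sigma = self.Gamma.T @ self.Gamma
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.a.shape != (self.n,):
            raise ModelError(f"a must have shape ({self.n},), got {self.a.shape}")
        if self.D.shape != (self.n, self.n):
            raise ModelError(f"D must be {self.n}x{self.n}, got {self.D.shape}")
        if self.Gamma.shape[1] != self.n:
            raise ModelError(
                f"Gamma must have {self.n} columns, got {self.Gamma.shape}"
            )
        if len(self.b) != self.n:
            raise ModelError("need one competition function per patch")
        self._validate_invariants()

    def _validate_invariants(self) -> None:
        rows = self.D.sum(axis=1)
        if np.any(np.abs(rows) > 1e-9):
            raise ModelError(f"dispersal rows must sum to 0, got {rows}")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-12):
            raise ModelError("Sigma must be symmetric")
        w = np.linalg.eigvalsh(self.Sigma)
        if w.min() < -1e-10 * max(np.abs(w).max(), 1.0):
            raise ModelError("Sigma must be positive semidefinite")
        for i, bi in enumerate(self.b):
            if abs(bi(0.0)) > 1e-12:
                raise ModelError(f"b_{i}(0) = {bi(0.0)} != 0")

    def b_vec(self, x: np.ndarray) -> np.ndarray:
        """Evaluate b = (b_1(x_1), ..., b_n(x_n)) elementwise.

        Fast path for linear competition b_i(x) = kappa_i * x; supports
        arrays with patch index on the last axis.
        """
        x = np.asarray(x, dtype=float)
        if self.competition_kind == "linear":
            return self.kappa * x
        out = np.empty_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for v in it:
            out[it.multi_index] = self.b[it.multi_index[-1]](float(v))
        return out

    def with_dispersal(self, D: np.ndarray) -> "PatchModel":
        return PatchModel(
            n=self.n, a=self.a.copy(), b=list(self.b), D=np.asarray(D, float),
            Gamma=self.Gamma.copy(), degenerate_flag=self.degenerate_flag,
            competition_kind=self.competition_kind,
            kappa=None if self.kappa is None else self.kappa.copy(),
        )


@dataclass
class TwoPatchSpec:
    """Two-patch model with linear competition and a shared noise correlation.

    ``d12``/``d21`` are the dispersal rates 1->2 and 2->1; ``sigma1``/``sigma2``
    the per-patch volatilities; ``rho`` the correlation of the two patches'
    environmental noise (|rho| = 1 collapses the driving noise to a single
    Brownian motion).
    """

    a1: float
    a2: float
    comp1: float = 1.0
    comp2: float = 1.0
    d12: float = 1.0
    d21: float = 1.0
    sigma1: float = 1.0
    sigma2: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.d12 < 0 or self.d21 < 0:
            raise ModelError("dispersal rates must be nonnegative")
        if abs(self.rho) > 1:
            raise ModelError(f"|rho| must be <= 1, got {self.rho}")

    @property
    def sigma_sq(self) -> tuple[float, float]:
        return self.sigma1**2, self.sigma2**2


# ---------------------------------------------------------------------------
# validation operations
# ---------------------------------------------------------------------------

def validate_dispersal(D: Sequence[Sequence[float]]) -> AssumptionReport:
    """Check that D is an irreducible dispersal matrix.

    Requires zero row sums, nonnegative off-diagonal entries, and strong
    connectivity of the digraph with an edge i->j whenever D_ij > 0 (the
    generator of an irreducible continuous-time Markov chain on patches).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ModelError(f"dispersal matrix must be square, got shape {D.shape}")
    if not np.all(np.isfinite(D)):
        raise ModelError("dispersal matrix must be finite")
    n = D.shape[0]
    problems = []
    rows = D.sum(axis=1)
    bad_rows = np.nonzero(np.abs(rows) > max(ROW_SUM_TOL, 1e-12 * np.abs(D).max()))[0]
    if bad_rows.size:
        problems.append(f"rows {bad_rows.tolist()} sum to {rows[bad_rows].tolist()}")
    off = D.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        i, j = np.nonzero(off < 0)
        problems.append(f"negative off-diagonal entries at {list(zip(i.tolist(), j.tolist()))}")
    if n > 1:
        adj = (off > 0).astype(int)
        ncomp, _ = connected_components(adj, directed=True, connection="strong")
        if ncomp > 1:
            problems.append(f"positive-rate digraph has {ncomp} strongly connected components")
    if problems:
        return AssumptionReport("irreducible_2_2", False, "; ".join(problems))
    return AssumptionReport(
        "irreducible_2_2", True, "zero row sums, nonnegative rates, strongly connected"
    )


def build_noise(
    sigma: Sequence[float] | None = None,
    rho: float | None = None,
    Gamma: Sequence[Sequence[float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Assemble the noise loading Gamma and covariance Sigma = Gamma^T Gamma.

    Either pass an explicit k x n loading matrix ``Gamma``, or per-patch
    volatilities ``sigma`` plus a common pairwise correlation ``rho``.
    Returns ``(Gamma, Sigma, degenerate_flag)`` where the flag marks
    rank(Sigma) < n. For two patches with rho = +-1 the returned Gamma has a
    single row: one Brownian motion drives both patches.
    """
    if Gamma is not None:
        G = np.atleast_2d(np.asarray(Gamma, dtype=float))
    else:
        s = np.atleast_1d(np.asarray(sigma, dtype=float))
        if np.any(s <= 0):
            raise ModelError(f"volatilities must be positive, got {s}")
        if rho is None:
            rho = 0.0
        if abs(rho) > 1:
            raise ModelError(f"|rho| must be <= 1, got {rho}")
        n = s.size
        if n == 1:
            G = s.reshape(1, 1)
        elif abs(abs(rho) - 1.0) < 1e-14:
            # perfectly (anti)correlated: one driving Brownian motion
            signs = np.ones(n)
            if rho < 0:
                signs[1::2] = -1.0
            G = (s * signs).reshape(1, n)
        else:
            C = np.full((n, n), rho, dtype=float)
            np.fill_diagonal(C, 1.0)
            L = np.linalg.cholesky(C)
            G = (np.diag(s) @ L).T  # Gamma^T Gamma = D_s C D_s
    S = G.T @ G
    sv = np.linalg.svd(S, compute_uv=False)
    degenerate = bool(np.sum(sv > RANK_RTOL * sv.max()) < S.shape[0]) if sv.max() > 0 else True
    return G, S, degenerate


def from_growth_functions(
    f: Sequence[Callable[[float], float]],
) -> tuple[np.ndarray, list[Callable[[float], float]]]:
    """Convert per-capita growth functions f_i into (a, b) form.

    a_i = f_i(0) and b_i(x) = f_i(0) - f_i(x), so b_i(0) = 0 by construction
    and X_i (a_i - b_i(X_i)) reproduces X_i f_i(X_i).
    """
    a = []
    b: list[Callable[[float], float]] = []
    for i, fi in enumerate(f):
        try:
            ai = float(fi(0.0))
        except Exception as exc:  # noqa: BLE001 - user callable
            raise ModelError(f"f_{i} not evaluable at 0: {exc}") from exc
        if not math.isfinite(ai):
            raise ModelError(f"f_{i}(0) is not finite")
        a.append(ai)
        b.append(lambda x, fi=fi, ai=ai: ai - fi(x))
    return np.asarray(a), b


def check_competition(
    model: PatchModel, grid_max: float = 1e4, grid_n: int = 400
) -> AssumptionReport:
    """Search for dissipativity constants (M_b, gamma_b).

    The admissibility condition requires the abundance-weighted mean of
    b_i(x_i) - a_i to exceed some gamma_b > 0 whenever the total abundance is
    at least M_b. A sufficient per-patch condition is
    inf_{x >= M} b_i(x) - a_i > gamma_b for every patch, which is what the
    grid search evaluates; linear competition with positive slopes passes
    analytically. An unbounded quantifier cannot be certified numerically,
    so failure to find a bound below ``grid_max`` is reported as
    inconclusive (passed = False).
    """
    aid = "competition_2_2"
    if model.competition_kind == "linear" and model.kappa is not None:
        if np.all(model.kappa > 0):
            # b_i(x) - a_i = kappa_i x - a_i >= kappa_min M - a_max
            kmin = float(model.kappa.min())
            amax = float(model.a.max())
            M = (amax + 1.0) / kmin if amax > -1.0 else 1.0 / kmin
            gamma = kmin * M - amax
            return AssumptionReport(
                aid, True, f"linear competition, analytic bound", M_b=M, gamma_b=gamma
            )
        return AssumptionReport(aid, False, "linear competition with nonpositive slope")
    # numeric search: find M such that min_i inf_{x in [M, grid_max]} b_i(x)-a_i > 0
    xs = np.geomspace(1e-6, grid_max, grid_n)
    vals = np.array([[bi(float(x)) - ai for x in xs] for bi, ai in zip(model.b, model.a)])
    # running minimum over the tail [x, grid_max] for each patch
    tail_min = np.minimum.accumulate(vals[:, ::-1], axis=1)[:, ::-1]
    worst = tail_min.min(axis=0)  # over patches
    ok = np.nonzero(worst > 0)[0]
    if ok.size:
        j = ok[0]
        gamma = float(worst[j] / 2)
        return AssumptionReport(
            aid, True, f"grid bound attained at x={xs[j]:.6g}",
            M_b=float(xs[j]), gamma_b=gamma,
        )
    return AssumptionReport(aid, False, f"inconclusive up to grid_max={grid_max:g}")


def make_two_patch(spec: TwoPatchSpec) -> PatchModel:
    """Build the two-patch model with linear competition from a spec."""
    D = np.array([[-spec.d12, spec.d12], [spec.d21, -spec.d21]], dtype=float)
    rep = validate_dispersal(D)
    if not rep.passed:
        raise ModelError(f"invalid dispersal: {rep.detail}")
    G, S, degen = build_noise(sigma=[spec.sigma1, spec.sigma2], rho=spec.rho)
    kappa = np.array([spec.comp1, spec.comp2], dtype=float)
    b = [lambda x, k=k: k * x for k in kappa]
    return PatchModel(
        n=2, a=np.array([spec.a1, spec.a2]), b=b, D=D, Gamma=G,
        degenerate_flag=degen, competition_kind="linear", kappa=kappa,
    )


# ---------------------------------------------------------------------------
# JSON config round trip
# ---------------------------------------------------------------------------

_TOP_KEYS = {"n", "a", "competition", "D", "noise"}


def model_to_json(model: PatchModel) -> str:
    if model.competition_kind != "linear":
        raise ModelError("only linear competition models are serializable")
    doc = {
        "n": model.n,
        "a": model.a.tolist(),
        "competition": {"type": "linear", "kappa": model.kappa.tolist()},
        "D": model.D.tolist(),
        "noise": {"type": "loading", "Gamma": model.Gamma.tolist()},
    }
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> PatchModel:
    doc = json.loads(text)
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ModelError(f"unknown config keys: {sorted(unknown)}")
    comp = doc["competition"]
    if comp.get("type") != "linear":
        raise ModelError(f"unsupported competition type {comp.get('type')!r}")
    kappa = np.asarray(comp["kappa"], dtype=float)
    b = [lambda x, k=k: k * x for k in kappa]
    noise = doc["noise"]
    if noise.get("type") == "loading":
        G, S, degen = build_noise(Gamma=noise["Gamma"])
    elif noise.get("type") == "volatility_correlation":
        G, S, degen = build_noise(sigma=noise["sigma"], rho=noise.get("rho", 0.0))
    else:
        raise ModelError(f"unsupported noise type {noise.get('type')!r}")
    return PatchModel(
        n=int(doc["n"]), a=np.asarray(doc["a"], dtype=float), b=b,
        D=np.asarray(doc["D"], dtype=float), Gamma=G, degenerate_flag=degen,
        competition_kind="linear", kappa=kappa,
    )
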