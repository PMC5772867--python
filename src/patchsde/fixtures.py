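"""Named model parameterizations used throughout tests and examples.

Each fixture is a validated model tagged with the phenomenon it exercises:
the two-patch dispersal/correlation sweep (growth rates 3 and 4, patch
variance 7, symmetric dispersal), its fully degenerate equal-volatility
variant, the synchronized-manifold slice, the scalar logistic benchmark,
and an exchangeable n-patch model.
"""

from __future__ import annotations

import math

from .model import ModelError, PatchModel, TwoPatchSpec, make_two_patch

__all__ = ["FIXTURES", "list_fixtures", "generate_fixture", "fixture_spec"]

_SWEEP_BASE = dict(a1=3.0, a2=4.0, sigma_sq=7.0)


def _sweep_spec(rho: float = 0.0, alpha: float = 1.0) -> TwoPatchSpec:
    s = math.sqrt(_SWEEP_BASE["sigma_sq"])
    return TwoPatchSpec(
        a1=_SWEEP_BASE["a1"], a2=_SWEEP_BASE["a2"], comp1=1.0, comp2=1.0,
        d12=alpha, d21=alpha, sigma1=s, sigma2=s, rho=rho,
    )


def _equal_sigma_spec(alpha: float = 1.0) -> TwoPatchSpec:
    # fully correlated equal-volatility two-patch system, symmetric dispersal
    return _sweep_spec(rho=1.0, alpha=alpha)


def _manifold_spec(a1: float = 2.0, d12: float = 0.5, d21: float = 0.5,
                sigma: float = 1.0, b: float = 1.0) -> TwoPatchSpec:
    # synchronized slice: 2(d21 - d12) = a2 - a1, equal sigma and competition
    a2 = a1 + 2 * (d21 - d12)
    return TwoPatchSpec(a1=a1, a2=a2, comp1=b, comp2=b, d12=d12, d21=d21,
                        sigma1=sigma, sigma2=sigma, rho=1.0)


def _single_patch_spec(a: float = 3.0, sigma_sq: float = 7.0):
    import numpy as np
    from .model import PatchModel

    return PatchModel(
        n=1, a=np.array([a]), b=[lambda x: x], D=np.zeros((1, 1)),
        Gamma=np.array([[math.sqrt(sigma_sq)]]), competition_kind="linear",
        kappa=np.array([1.0]),
    )


def _symmetric_n(n: int = 3, a: float = 1.0, sigma_sq: float = 1.0,
                 d: float = 1.0, kappa: float = 1.0) -> PatchModel:
    import numpy as np

    D = np.full((n, n), d / (n - 1))
    np.fill_diagonal(D, -d)
    b = [lambda x, k=kappa: k * x for _ in range(n)]
    return PatchModel(
        n=n, a=np.full(n, a), b=b, D=D,
        Gamma=math.sqrt(sigma_sq) * np.eye(n),
        competition_kind="linear", kappa=np.full(n, kappa),
    )


FIXTURES = {
    "two_patch_sweep": {
        "builder": _sweep_spec,
        "tag": "two-patch dispersal/correlation sweep (r vs dispersal)",
        "kind": "spec",
    },
    "degenerate_equal_sigma": {
        "builder": _equal_sigma_spec,
        "tag": "degenerate equal-volatility case: point-mass proportions, closed-form r",
        "kind": "spec",
    },
    "synchronized_manifold": {
        "builder": _manifold_spec,
        "tag": "synchronized slice: invariant law concentrates on the diagonal",
        "kind": "spec",
    },
    "single_patch": {
        "builder": _single_patch_spec,
        "tag": "scalar stochastic logistic benchmark: r = a - sigma^2/2",
        "kind": "model",
    },
    "symmetric_n": {
        "builder": _symmetric_n,
        "tag": "exchangeable n-patch model (symmetry checks)",
        "kind": "model",
    },
}


def list_fixtures() -> dict[str, str]:
    return {name: info["tag"] for name, info in FIXTURES.items()}


def fixture_spec(name: str, **overrides) -> TwoPatchSpec:
    """Return the TwoPatchSpec behind a two-patch fixture."""
    info = FIXTURES.get(name)
    if info is None or info["kind"] != "spec":
        raise ModelError(
            f"no two-patch spec fixture {name!r}; available: "
            + ", ".join(k for k, v in FIXTURES.items() if v["kind"] == "spec")
        )
    return info["builder"](**overrides)


def generate_fixture(name: str, **overrides):
    """Build and validate a named fixture model (overrides merged shallowly)."""
    info = FIXTURES.get(name)
    if info is None:
        raise ModelError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        )
    built = info["builder"](**overrides)
    if info["kind"] == "spec":
        return make_two_patch(built)
    return built
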