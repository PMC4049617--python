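"""Synthetic fixtures: an analytically solvable bistable toy system,
brute-force root scanners, and randomized configurations.

The toy model shares the feedback-activation geometry of the F6P node (a
Hill-type positive loop against linear removal), so its exactly known root
structure exercises the same fold/near-tangency situations the real solver
faces; its steady states are the nonnegative real roots of a low-degree
polynomial and their stability follows from the sign of the scalar
derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import ModelConfig
from .state import ENZYMES


@dataclass(frozen=True)
class ToyBistableModel:
    """One-dimensional system dx/dt = b x^n / (K^n + x^n) + a - c x."""

    a: float = 0.01
    b: float = 1.0
    c: float = 0.5
    K: float = 1.0
    n: int = 2

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0 or self.K <= 0 or self.n < 2:
            raise ValueError("require a, b, c >= 0, K > 0, integer n >= 2")

    def rhs(self, x: float) -> float:
        xn = x ** self.n
        return self.b * xn / (self.K ** self.n + xn) + self.a - self.c * x

    def drhs(self, x: float) -> float:
        kn = self.K ** self.n
        xn = x ** self.n
        return (self.b * self.n * kn * x ** (self.n - 1) / (kn + xn) ** 2
                - self.c)

    def polynomial(self) -> np.ndarray:
        """Coefficients (highest degree first) whose nonnegative real roots
        are the steady states: -c x^(n+1) + (a+b) x^n - c K^n x + a K^n."""
        coeffs = np.zeros(self.n + 2)
        coeffs[0] = -self.c
        coeffs[1] = self.a + self.b
        coeffs[-2] = -self.c * self.K ** self.n
        coeffs[-1] = self.a * self.K ** self.n
        return coeffs


#: Bundled parameter set with exactly three positive steady states (n = 2).
BUNDLED_BISTABLE = ToyBistableModel(a=0.01, b=1.0, c=0.5, K=1.0, n=2)


def toy_steady_states(model: ToyBistableModel,
                      imag_tol: float = 1e-9) -> list[tuple[float, bool]]:
    """Exact steady states of the toy model with analytic stability.

    Roots come from the companion-matrix polynomial solve; a state is stable
    iff d(rhs)/dx < 0 there.
    """
    roots = np.roots(model.polynomial())
    xs: list[float] = []
    for r in roots:
        if abs(r.imag) > imag_tol * max(1.0, abs(r)) or r.real < -imag_tol:
            continue
        x = max(float(r.real), 0.0)
        # a double root (fold tangency) is one steady state
        if any(abs(x - seen) <= 1e-7 * (1.0 + abs(x)) for seen in xs):
            continue
        xs.append(x)
    return sorted((x, model.drhs(x) < 0) for x in xs)


def brute_force_roots(fun, lo: float, hi: float, resolution: float,
                      max_refine: int = 6) -> list[float]:
    """All roots of a scalar function on [lo, hi] by sign-change scanning.

    The grid is refined (halving the resolution) up to ``max_refine`` times
    until the root count stabilizes, guarding against adjacent sign changes
    hiding inside one cell.  Serves as the independent oracle for the
    multistart and reduction solvers.
    """
    from scipy.optimize import brentq

    def scan(res: float) -> list[float]:
        xs = np.arange(lo, hi + res, res)
        vals = np.array([fun(x) for x in xs])
        roots = []
        for i in range(len(xs) - 1):
            va, vb = vals[i], vals[i + 1]
            if not (math.isfinite(va) and math.isfinite(vb)):
                continue
            if va == 0.0:
                roots.append(float(xs[i]))
            elif va * vb < 0:
                roots.append(float(brentq(fun, xs[i], xs[i + 1],
                                          xtol=1e-13, rtol=1e-15)))
        if math.isfinite(vals[-1]) and vals[-1] == 0.0:
            roots.append(float(xs[-1]))
        return roots

    res = resolution
    roots = scan(res)
    for _ in range(max_refine):
        finer = scan(res / 2.0)
        if len(finer) == len(roots):
            return finer
        roots, res = finer, res / 2.0
    return roots


def brute_force_roots_2d(fun, bounds, resolution, max_refine: int = 4
                         ) -> list[tuple[float, float]]:
    """Roots of a 2-D system by nested scanning.

    ``fun(x, y) -> (f1, f2)``: the inner variable y is solved from f2 = 0 by
    1-D scanning at each x, then f1 is scanned along the resulting slice.
    Intended for reduced two-unknown subsystems (e.g. the F6P node with
    dynamic F6P and F16BP).
    """
    (x_lo, x_hi), (y_lo, y_hi) = bounds
    rx, ry = resolution

    def inner_roots(x: float) -> list[float]:
        return brute_force_roots(lambda y: fun(x, y)[1], y_lo, y_hi, ry,
                                 max_refine)

    def outer(x: float) -> float:
        ys = inner_roots(x)
        if not ys:
            return float("nan")
        # follow the slice through the lowest inner root; additional inner
        # branches are picked up by the scan over their own sign changes
        return fun(x, ys[0])[0]

    roots = []
    for x in brute_force_roots(outer, x_lo, x_hi, rx, max_refine):
        for y in inner_roots(x):
            if abs(fun(x, y)[0]) < 1e-7:
                roots.append((x, y))
    return roots


def random_config(seed: int, log10_range: float = 1.0,
                  base: ModelConfig | None = None) -> ModelConfig:
    """Randomized enzyme-level perturbation of a base configuration.

    Each enzyme level is multiplied by 10^u with u uniform on
    [-log10_range, +log10_range]; deterministic per seed.
    """
    from .catalog import build_config

    if base is None:
        base = build_config("PFKL", "PKM2", 10.0)
    rng = np.random.default_rng(seed)
    factors = 10.0 ** rng.uniform(-log10_range, log10_range, size=len(ENZYMES))
    levels = {enz: base.levels.get(enz) * float(f)
              for enz, f in zip(ENZYMES, factors)}
    return base.with_levels(**levels)
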