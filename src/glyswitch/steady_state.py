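"""Steady-state enumeration and linear stability classification.

``find_steady_states`` follows the classical recipe: many pseudorandom
initial guesses handed to a damped Newton-type root finder on the
12-dimensional balance equations, followed by positivity/residual
screening, deduplication and eigenvalue analysis of the finite-difference
Jacobian.  The scalar flux reduction of :mod:`glyswitch.reduction` is
available as a second enumeration method and as the seed generator for the
default hybrid mode ("reduction roots polished by Newton, plus multistart
top-up"), and the two routes cross-check each other in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root as _scipy_root

from .catalog import ModelConfig
from .errors import NumericalError
from .model import flux_balance_residuals, fluxes, rhs_raw
from .reduction import enumerate_steady_states as _reduction_states
from .state import N_SPECIES, SPECIES, MetaboliteState

#: Default stability margin (1/h): a state is stable only if every
#: eigenvalue real part is below -EPS_STAB, unstable only if some real part
#: exceeds +EPS_STAB, and "marginal" otherwise.
EPS_STAB = 1e-9

#: Default residual bound (mM/h) for an accepted root.
RESIDUAL_TOL = 1e-8

#: Default relative tolerance under which two roots are considered the same.
DEDUPE_RTOL = 1e-4


@dataclass(frozen=True)
class SteadyStateSolution:
    """One root of the balance equations with its stability diagnosis."""

    state: MetaboliteState
    flux: float                     # upper-glycolysis flux J_PFK (mM/h)
    flux_hk: float                  # J_HK (mM/h); equals flux at a true root
    eigenvalues: np.ndarray = field(repr=False)
    stability: str = "unknown"      # "stable" | "unstable" | "marginal"
    residual_norm: float = np.inf   # max |rhs| (mM/h)
    start_index: int = -1           # multistart guess that produced the root

    @property
    def stable(self) -> bool:
        return self.stability == "stable"

    @property
    def max_real_eigenvalue(self) -> float:
        return float(np.max(self.eigenvalues.real))


def jacobian(state: MetaboliteState, config: ModelConfig,
             step: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the rhs at ``state``.

    Central differences with a relative step (absolute floor 1e-9 mM for
    near-zero concentrations).
    """
    y0 = state.as_array()
    n = N_SPECIES
    jac = np.empty((n, n))
    env, cfg = config.env, config
    for k in range(n):
        h = max(step * abs(y0[k]), 1e-9)
        yp, ym = y0.copy(), y0.copy()
        yp[k] += h
        ym[k] = max(ym[k] - h, 0.0)
        col = (rhs_raw(yp, env, cfg) - rhs_raw(ym, env, cfg)) / (yp[k] - ym[k])
        if not np.all(np.isfinite(col)):
            raise NumericalError(
                f"non-finite Jacobian column for species {SPECIES[k]}")
        jac[:, k] = col
    return jac


def classify(eigenvalues: np.ndarray, epsilon_stab: float = EPS_STAB) -> str:
    """Stability label from Jacobian eigenvalues.

    "marginal" flags a leading real part within the stability margin; scans
    treat it as unresolved and refine their grids.
    """
    lead = float(np.max(np.asarray(eigenvalues).real))
    if lead < -epsilon_stab:
        return "stable"
    if lead > epsilon_stab:
        return "unstable"
    return "marginal"


def dedupe(roots: list[np.ndarray], residuals: list[float] | None = None,
           rel_tol: float = DEDUPE_RTOL) -> list[int]:
    """Indices of unique roots; duplicates keep the lowest-residual member.

    Two roots are the same when the maximum relative component difference is
    below ``rel_tol`` (absolute floor 1e-9 mM for near-zero components).
    """
    if residuals is None:
        residuals = [0.0] * len(roots)
    order = sorted(range(len(roots)), key=lambda i: residuals[i])
    kept: list[int] = []
    for i in order:
        a = roots[i]
        is_dup = False
        for j in kept:
            b = roots[j]
            scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-9)
            if np.max(np.abs(a - b) / scale) < rel_tol:
                is_dup = True
                break
        if not is_dup:
            kept.append(i)
    return sorted(kept)


def _polish(y0: np.ndarray, config: ModelConfig,
            relax: bool = False) -> np.ndarray | None:
    """Newton-polish a candidate root; optionally pre-relax first.

    Newton-type iterations rarely converge from arbitrary pseudorandom
    states of this stiff system, so multistart guesses are first relaxed a
    short time along the flow (which lands them near an attractor) and then
    polished.  Pre-relaxation is skipped for candidates that are already
    near a root (e.g. from the flux reduction), and implies that the
    multistart route recovers the stable steady states; unstable saddles
    enter through the reduction enumeration.
    """
    env = config.env

    def fun(y):
        try:
            return rhs_raw(y, env, config)
        except (OverflowError, FloatingPointError, ArithmeticError):
            return np.full(y0.shape, 1e12)

    if relax:
        from scipy.integrate import solve_ivp
        ivp = solve_ivp(lambda t, y: fun(y), (0.0, 2.0), y0,
                        method="LSODA", rtol=1e-6, atol=1e-9)
        if not ivp.success:
            return None
        y0 = np.maximum(ivp.y[:, -1], 0.0)
    sol = _scipy_root(fun, y0, method="hybr", options={"xtol": 1e-13})
    if not sol.success:
        return None
    y = np.maximum(sol.x, 0.0)
    if not np.all(np.isfinite(y)):
        return None
    return y


def _solution_from_root(y: np.ndarray, config: ModelConfig,
                        epsilon_stab: float, start_index: int
                        ) -> SteadyStateSolution:
    state = MetaboliteState.from_array(np.maximum(y, 0.0))
    resid = float(np.max(np.abs(rhs_raw(y, config.env, config))))
    v = fluxes(state, config.env, config)
    eig = np.linalg.eigvals(jacobian(state, config))
    return SteadyStateSolution(state=state, flux=v["PFK"], flux_hk=v["HK"],
                               eigenvalues=eig,
                               stability=classify(eig, epsilon_stab),
                               residual_norm=resid, start_index=start_index)


def find_steady_states(glucose: float, config: ModelConfig,
                       n_starts: int = 200, seed: int = 0,
                       method: str = "hybrid",
                       residual_tol: float = RESIDUAL_TOL,
                       dedupe_rtol: float = DEDUPE_RTOL,
                       epsilon_stab: float = EPS_STAB,
                       uniform_starts: bool = False,
                       ) -> list[SteadyStateSolution]:
    """All positive real steady states at one glucose level, sorted by flux.

    method:
      "multistart" - pseudorandom initial guesses only (log-uniform over
          [1e-4, 10] mM per species by default; ``uniform_starts`` switches
          to standard-uniform over [0, 10] mM).
      "reduction"  - scalar flux-reduction enumeration only.
      "hybrid"     - reduction roots plus multistart top-up (default).

    Deterministic for fixed (glucose, config, n_starts, seed).
    """
    if glucose < 0:
        raise ValueError("glucose must be >= 0")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    config = config.with_env(GLC_EXT=glucose)
    candidates: list[np.ndarray] = []
    if method in ("reduction", "hybrid"):
        for st in _reduction_states(glucose, config):
            y = _polish(st.as_array(), config)
            candidates.append(y if y is not None else st.as_array())
    if method in ("multistart", "hybrid"):
        rng = np.random.default_rng(seed)
        if uniform_starts:
            starts = rng.uniform(0.0, 10.0, size=(n_starts, N_SPECIES))
        else:
            starts = 10.0 ** rng.uniform(-4, 1, size=(n_starts, N_SPECIES))
        for y0 in starts:
            y = _polish(y0, config, relax=True)
            if y is not None:
                candidates.append(y)
    elif method not in ("reduction",):
        if method != "hybrid":
            raise ValueError(f"unknown method {method!r}")

    # screen: residual + positivity
    roots, residuals = [], []
    for y in candidates:
        r = float(np.max(np.abs(rhs_raw(y, config.env, config))))
        if r < residual_tol:
            roots.append(np.maximum(y, 0.0))
            residuals.append(r)
    keep = dedupe(roots, residuals, dedupe_rtol)
    solutions = [_solution_from_root(roots[i], config, epsilon_stab, i)
                 for i in keep]
    solutions.sort(key=lambda s: s.flux)
    return solutions


def balance_report(sol: SteadyStateSolution, config: ModelConfig) -> dict[str, float]:
    """Relative flux-balance residuals of a solution (diagnostics)."""
    return flux_balance_residuals(sol.state, config.env, config)
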