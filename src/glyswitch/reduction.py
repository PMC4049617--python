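"""Steady-state enumeration by reduction to scalar root problems.

At a steady state the flux relations of the pathway chain determine every
intermediate from the upper-glycolysis flux J alone: pyruvate from the sink
balance, PEP from the PK balance (with the lower chain inverted
analytically back to F16BP), F6P from the PFK balance with F26BP at its
internal PFKFB zero, and G6P / internal glucose from PGI / GLUT.  The
remaining hexokinase balance R(J) = v_HK - J is a scalar function whose
zeros are exactly the steady states of the 12-dimensional system.  Scanning
R on a fine flux grid enumerates *all* steady states, including unstable
ones, without multistart luck; the multistart solver in
:mod:`glyswitch.steady_state` serves as the independent cross-check.

The isolated F6P node (PFK + ALDO, optionally + PFKFB, trioses fixed) is
handled the same way with F16BP as the scan variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import ratelaws as rl
from .catalog import ModelConfig
from .state import MetaboliteState

_NAN = float("nan")


# ---------------------------------------------------------------------------
# F6P node (figure-1-style subsystem)
# ---------------------------------------------------------------------------

#: Triose concentrations held fixed in the isolated node (mM).
NODE_DHAP = 0.04
NODE_GAP = 0.02


def node_pfk_rate(f6p: float, f16bp: float, config: ModelConfig,
                  with_pfkfb: bool) -> float:
    """PFK rate in the node, with F26BP at its PFKFB zero (or absent)."""
    env = config.env
    if with_pfkfb:
        f26 = rl.pfkfb_f26bp_star(f6p, env.ATP, env.PEP_NODE, config.pfkfb)
    else:
        f26 = 0.0
    return rl.mixture_rate_pfk(config.pfk_fractions, f6p, env.ATP, f16bp, f26,
                               env.AMP, config.pfk_catalog, config.levels.PFK,
                               config.chain.v_pfk)


def node_residual(f6p: float, f16bp: float, config: ModelConfig,
                  with_pfkfb: bool = True) -> float:
    """d[F16BP]/dt of the node: PFK production minus ALDO consumption."""
    v_pfk = node_pfk_rate(f6p, f16bp, config, with_pfkfb)
    v_aldo = rl.rate_aldo(f16bp, NODE_DHAP, NODE_GAP, config.chain,
                          config.levels.ALDO)
    return v_pfk - v_aldo


@dataclass(frozen=True)
class NodeState:
    """One steady state of the F6P node."""

    f6p: float
    f16bp: float
    flux: float          # J_PFK = J_ALDO, mM/h
    stable: bool


def node_steady_states(f6p: float, config: ModelConfig,
                       with_pfkfb: bool = True,
                       x_max: float = 1000.0, n_grid: int = 800) -> list[NodeState]:
    """All steady states of the node at one F6P value (sign-change scan).

    Stability follows the sign of d(residual)/d[F16BP] at the root: the node
    is one-dimensional, so a negative derivative means stable.
    """
    if f6p < 0:
        raise ValueError("F6P must be >= 0")
    grid = np.concatenate([[0.0], np.geomspace(1e-6, x_max, n_grid)])
    vals = np.array([node_residual(f6p, x, config, with_pfkfb) for x in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if not (math.isfinite(a) and math.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(lambda x: node_residual(f6p, x, config, with_pfkfb),
                                grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    out = []
    for x in sorted(roots):
        h = max(1e-8, 1e-6 * x)
        slope = (node_residual(f6p, x + h, config, with_pfkfb)
                 - node_residual(f6p, max(x - h, 0.0), config, with_pfkfb)) / (
                     x + h - max(x - h, 0.0))
        flux = rl.rate_aldo(x, NODE_DHAP, NODE_GAP, config.chain,
                            config.levels.ALDO)
        out.append(NodeState(f6p=f6p, f16bp=x, flux=flux, stable=slope < 0))
    # merge numerically coincident roots
    merged: list[NodeState] = []
    for st in out:
        if merged and abs(st.f16bp - merged[-1].f16bp) <= 1e-9 * (1 + st.f16bp):
            continue
        merged.append(st)
    return merged


def node_switch_points(config: ModelConfig, with_pfkfb: bool = True,
                       f6p_max: float = 1.0, coarse: int = 201,
                       refine_to: float = 0.0005) -> tuple[float | None, float | None]:
    """(switch_up, switch_down) F6P concentrations of the node, or None.

    switch_up is the largest F6P at which the low-flux branch still exists;
    switch_down the smallest at which the high branch exists.  Both are
    located by bisection on the count of coexisting states.
    """
    grid = np.linspace(1e-4, f6p_max, coarse)
    counts = np.array([len(node_steady_states(f, config, with_pfkfb))
                       for f in grid])
    multi = counts >= 3
    if not multi.any():
        return None, None

    def count(f):
        return len(node_steady_states(f, config, with_pfkfb))

    i_hi = int(np.nonzero(multi)[0][-1])
    i_lo = int(np.nonzero(multi)[0][0])
    # refine upper edge (switch-up)
    lo, hi = grid[i_hi], grid[min(i_hi + 1, len(grid) - 1)]
    if i_hi == len(grid) - 1:
        switch_up = grid[-1]
    else:
        while hi - lo > refine_to:
            mid = 0.5 * (lo + hi)
            if count(mid) >= 3:
                lo = mid
            else:
                hi = mid
        switch_up = 0.5 * (lo + hi)
    # refine lower edge (switch-down)
    lo, hi = grid[max(i_lo - 1, 0)], grid[i_lo]
    if i_lo == 0:
        switch_down = grid[0]
    else:
        while hi - lo > refine_to:
            mid = 0.5 * (lo + hi)
            if count(mid) >= 3:
                hi = mid
            else:
                lo = mid
        switch_down = 0.5 * (lo + hi)
    return float(switch_up), float(switch_down)


# ---------------------------------------------------------------------------
# full model: scalar reduction in the upper-glycolysis flux J
# ---------------------------------------------------------------------------

def _solve_pyruvate(j2: float, config: ModelConfig, pyr_max: float = 200.0) -> float:
    """Pyruvate level at which the three sinks carry flux ``j2`` (mM)."""
    env, p, lv = config.env, config.chain, config.levels

    def sinks(pyr: float) -> float:
        return (rl.rate_ldh(pyr, env.NAD, env.NADH, env.LAC, p, lv.LDH)
                + rl.rate_mito(pyr, env.PYR_M, p, lv.MCT_MITO)
                + rl.rate_ala_sink(pyr, env.ALA, p, lv.ALA_SINK) - j2)

    lo, hi = 0.0, pyr_max
    if sinks(lo) > 0 or sinks(hi) < 0:
        return _NAN
    return brentq(sinks, lo, hi, xtol=1e-13, rtol=1e-15)


def _lower_chain_from_pep(pep: float, j: float, config: ModelConfig
                          ) -> tuple[float, float, float, float, float, float]:
    """Invert ENO...ALDO for (PG2, PG3, BPG13, GAP, DHAP, F16BP) at flux j.

    Lower glycolysis carries 2j; TPI carries j.  Returns NaNs when any step
    cannot sustain the requested flux.
    """
    env, p, lv = config.env, config.chain, config.levels
    j2 = 2.0 * j
    pg2 = rl.eno_invert_pg2(j2, pep, p, lv.ENO)
    if not math.isfinite(pg2):
        return (_NAN,) * 6
    pg3 = rl.pgam_invert_pg3(j2, pg2, p, lv.PGAM)
    if not math.isfinite(pg3):
        return (_NAN,) * 6
    bpg = rl.pgk_invert_bpg(j2, pg3, env.ADP, env.ATP, p, lv.PGK)
    if not math.isfinite(bpg):
        return (_NAN,) * 6
    gap = rl.gapdh_invert_gap(j2, bpg, env.NAD, env.NADH, p, lv.GAPDH)
    if not math.isfinite(gap):
        return (_NAN,) * 6
    dhap = rl.tpi_invert_dhap(j, gap, p, lv.TPI)
    if not math.isfinite(dhap):
        return (_NAN,) * 6
    f16bp = rl.aldo_invert_f16bp(j, dhap, gap, p, lv.ALDO)
    if not math.isfinite(f16bp):
        return (_NAN,) * 6
    return pg2, pg3, bpg, gap, dhap, f16bp


def _solve_pep(j: float, pyr: float, config: ModelConfig,
               pep_max: float = 100.0) -> float:
    """PEP at which PK carries 2j, with F16BP slaved to PEP via the chain."""
    env, p, lv = config.env, config.chain, config.levels
    j2 = 2.0 * j

    def resid(pep: float) -> float:
        chain = _lower_chain_from_pep(pep, j, config)
        f16bp = chain[5]
        if not math.isfinite(f16bp):
            return _NAN
        return rl.rate_pk(pep, env.ADP, f16bp, env.ATP, pyr,
                          config.pk_iso, lv.PK, p.v_pk) - j2

    lo = 1e-12
    r_lo = resid(lo)
    if not math.isfinite(r_lo) or r_lo > 0:
        return _NAN
    # expand the bracket geometrically; resid is monotone increasing in PEP
    hi = 1e-3
    r_hi = resid(hi)
    while hi < pep_max and (not math.isfinite(r_hi) or r_hi < 0):
        if not math.isfinite(r_hi):
            return _NAN
        hi *= 2.0
        r_hi = resid(hi)
    if not math.isfinite(r_hi) or r_hi < 0:
        return _NAN
    return brentq(resid, lo, hi, xtol=1e-13, rtol=1e-15)


def _solve_f6p(j: float, f16bp: float, pep: float, config: ModelConfig,
               f6p_max: float = 500.0) -> float:
    """F6P at which PFK carries flux j (F26BP at its PFKFB zero)."""
    env, p, lv = config.env, config.chain, config.levels

    def resid(f6p: float) -> float:
        f26 = rl.pfkfb_f26bp_star(f6p, env.ATP, pep, config.pfkfb)
        return rl.mixture_rate_pfk(config.pfk_fractions, f6p, env.ATP, f16bp,
                                   f26, env.AMP, config.pfk_catalog, lv.PFK,
                                   p.v_pfk) - j

    if j <= 0:
        return 0.0
    if resid(f6p_max) < 0:
        return _NAN
    return brentq(resid, 0.0, f6p_max, xtol=1e-14, rtol=1e-15)


def reduced_state(j: float, glucose: float, config: ModelConfig
                  ) -> MetaboliteState | None:
    """Candidate steady state carrying upper flux ``j`` (HK balance aside).

    Returns None when some step cannot sustain the flux.
    """
    env, p, lv = config.env, config.chain, config.levels
    pyr = _solve_pyruvate(2.0 * j, config)
    if not math.isfinite(pyr):
        return None
    pep = _solve_pep(j, pyr, config)
    if not math.isfinite(pep):
        return None
    pg2, pg3, bpg, gap, dhap, f16bp = _lower_chain_from_pep(pep, j, config)
    if not math.isfinite(f16bp):
        return None
    f6p = _solve_f6p(j, f16bp, pep, config)
    if not math.isfinite(f6p):
        return None
    f26 = rl.pfkfb_f26bp_star(f6p, env.ATP, pep, config.pfkfb)
    g6p = rl.pgi_invert_g6p(j, f6p, p, lv.PGI)
    if not math.isfinite(g6p):
        return None
    glc_in = rl.glut_invert_internal(j, glucose, p, lv.GLUT)
    if not math.isfinite(glc_in):
        return None
    return MetaboliteState(GLC=glc_in, G6P=g6p, F6P=f6p, F16BP=f16bp,
                           F26BP=f26, DHAP=dhap, GAP=gap, BPG13=bpg,
                           PG3=pg3, PG2=pg2, PEP=pep, PYR=pyr)


def flux_residual(j: float, glucose: float, config: ModelConfig) -> float:
    """Hexokinase balance R(j) = v_HK - j along the reduced manifold."""
    state = reduced_state(j, glucose, config)
    if state is None:
        return _NAN
    return rl.rate_hk(state.GLC, config.env.ATP, state.G6P, config.chain,
                      config.levels.HK) - j


def flux_cap(glucose: float, config: ModelConfig) -> float:
    """Upper bound on the steady-state upper-glycolysis flux (mM/h)."""
    env, p, lv = config.env, config.chain, config.levels
    caps = [
        lv.GLUT * p.v_glut * glucose / (p.k_glut + glucose),
        lv.HK * p.v_hk * (env.ATP / (p.km_hk_atp + env.ATP)),
        lv.PGI * p.v_pgi * 0.99,
        lv.PFK * p.v_pfk,
        0.5 * lv.PK * p.v_pk * (env.ADP / (config.pk_iso.km_adp + env.ADP)),
        0.5 * lv.ENO * p.v_eno * 0.99,
        0.5 * lv.PGAM * p.v_pgam * 0.99,
    ]
    return max(min(caps), 0.0)


def enumerate_flux_roots(glucose: float, config: ModelConfig,
                         n_grid: int = 400) -> list[float]:
    """All zeros of R(j) on (0, flux cap): the steady-state fluxes."""
    cap = flux_cap(glucose, config)
    if cap <= 0:
        return []
    grid = np.concatenate([np.geomspace(cap * 1e-7, cap * 0.1, n_grid // 4),
                           np.linspace(cap * 0.1, cap * 0.999999, n_grid)])
    vals = np.array([flux_residual(j, glucose, config) for j in grid])
    roots: list[float] = []
    fun = lambda j: flux_residual(j, glucose, config)  # noqa: E731
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if math.isfinite(a) and not math.isfinite(b) and a > 0:
            # R runs into the demand-ceiling boundary (F6P -> infinity, so
            # supply -> 0 and R -> negative) before the next grid point:
            # bisect for the last feasible flux and look for the crossing.
            lo, hi = grid[i], grid[i + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if math.isfinite(fun(mid)):
                    lo = mid
                else:
                    hi = mid
            b_edge = fun(lo)
            if math.isfinite(b_edge) and a * b_edge < 0:
                roots.append(brentq(fun, grid[i], lo, xtol=1e-12, rtol=1e-15))
            continue
        if not (math.isfinite(a) and math.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(fun, grid[i], grid[i + 1],
                                xtol=1e-12, rtol=1e-15))
    merged: list[float] = []
    for r in sorted(roots):
        if merged and abs(r - merged[-1]) <= 1e-8 * (1 + r):
            continue
        merged.append(r)
    return merged


def enumerate_steady_states(glucose: float, config: ModelConfig,
                            n_grid: int = 400) -> list[MetaboliteState]:
    """All steady states of the full model at one glucose level."""
    states = []
    for j in enumerate_flux_roots(glucose, config, n_grid):
        st = reduced_state(j, glucose, config)
        if st is not None:
            states.append(st)
    return states
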