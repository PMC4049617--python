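"""Flux evaluation and the ODE right-hand side for the 12 balanced species.

Stoichiometry: one F16BP splits into DHAP + GAP, so the triose pool feeds
GAPDH at twice the carbon flux of upper glycolysis; the cytosolic pyruvate
balance is PK minus LDH, mitochondrial transport and the alanine-linked
sink.  All other concentrations (nucleotides, redox pair, ions, external
pools) are held in the :class:`~glyswitch.state.Environment`.
"""

from __future__ import annotations

import math

import numpy as np

from . import ratelaws as rl
from .catalog import ModelConfig
from .errors import ConfigurationError, NumericalError
from .state import ENZYMES, N_SPECIES, SPECIES, Environment, MetaboliteState


def fluxes(state: MetaboliteState, env: Environment, config: ModelConfig,
           ) -> dict[str, float]:
    """All reaction rates (mM/h) at one state.

    The PFKFB entry is the net F26BP production rate (kinase minus
    phosphatase); the two domains are additionally reported under
    ``PFKFB_KINASE`` and ``PFKFB_PHOSPHATASE``.
    """
    lv = config.levels
    p = config.chain
    s = state
    v_kin = rl.rate_pfkfb_kinase(s.F6P, env.ATP, s.PEP, config.pfkfb, lv.PFKFB)
    v_pho = rl.rate_pfkfb_phosphatase(s.F26BP, config.pfkfb, lv.PFKFB)
    out = {
        "GLUT": rl.rate_glut(env.GLC_EXT, s.GLC, p, lv.GLUT),
        "HK": rl.rate_hk(s.GLC, env.ATP, s.G6P, p, lv.HK),
        "PGI": rl.rate_pgi(s.G6P, s.F6P, p, lv.PGI),
        "PFK": rl.mixture_rate_pfk(config.pfk_fractions, s.F6P, env.ATP,
                                   s.F16BP, s.F26BP, env.AMP,
                                   config.pfk_catalog, lv.PFK, p.v_pfk),
        "PFKFB": v_kin - v_pho,
        "PFKFB_KINASE": v_kin,
        "PFKFB_PHOSPHATASE": v_pho,
        "ALDO": rl.rate_aldo(s.F16BP, s.DHAP, s.GAP, p, lv.ALDO),
        "TPI": rl.rate_tpi(s.DHAP, s.GAP, p, lv.TPI),
        "GAPDH": rl.rate_gapdh(s.GAP, s.BPG13, env.NAD, env.NADH, p, lv.GAPDH),
        "PGK": rl.rate_pgk(s.BPG13, s.PG3, env.ADP, env.ATP, p, lv.PGK),
        "PGAM": rl.rate_pgam(s.PG3, s.PG2, p, lv.PGAM),
        "ENO": rl.rate_eno(s.PG2, s.PEP, p, lv.ENO),
        "PK": rl.rate_pk(s.PEP, env.ADP, s.F16BP, env.ATP, s.PYR,
                         config.pk_iso, lv.PK, p.v_pk),
        "LDH": rl.rate_ldh(s.PYR, env.NAD, env.NADH, env.LAC, p, lv.LDH),
        "MCT_MITO": rl.rate_mito(s.PYR, env.PYR_M, p, lv.MCT_MITO),
        "ALA_SINK": rl.rate_ala_sink(s.PYR, env.ALA, p, lv.ALA_SINK),
    }
    for enzyme, value in out.items():
        if not math.isfinite(value):
            raise NumericalError(f"non-finite rate for {enzyme}: {value!r}")
    return out


def rate_chain(enzyme_id: str, state: MetaboliteState, env: Environment,
               config: ModelConfig) -> float:
    """Rate of one enzyme/transport step by name (mM/h)."""
    if enzyme_id not in ENZYMES and enzyme_id not in ("PFKFB_KINASE",
                                                      "PFKFB_PHOSPHATASE"):
        raise ConfigurationError(
            f"unknown enzyme {enzyme_id!r}; valid: {list(ENZYMES)}")
    return fluxes(state, env, config)[enzyme_id]


def rhs_from_fluxes(v: dict[str, float]) -> np.ndarray:
    """Species time derivatives (mM/h) from a flux dict."""
    return np.array([
        v["GLUT"] - v["HK"],                       # GLC
        v["HK"] - v["PGI"],                        # G6P
        v["PGI"] - v["PFK"] - v["PFKFB"],          # F6P (PFKFB net borrows F6P)
        v["PFK"] - v["ALDO"],                      # F16BP
        v["PFKFB"],                                # F26BP
        v["ALDO"] - v["TPI"],                      # DHAP
        v["ALDO"] + v["TPI"] - v["GAPDH"],         # GAP
        v["GAPDH"] - v["PGK"],                     # BPG13
        v["PGK"] - v["PGAM"],                      # PG3
        v["PGAM"] - v["ENO"],                      # PG2
        v["ENO"] - v["PK"],                        # PEP
        v["PK"] - v["LDH"] - v["MCT_MITO"] - v["ALA_SINK"],  # PYR
    ])


def rhs(state: MetaboliteState | np.ndarray, env: Environment,
        config: ModelConfig) -> np.ndarray:
    """Time derivatives (mM/h) of the 12 balanced intermediates."""
    if not isinstance(state, MetaboliteState):
        state = MetaboliteState.from_array(state)
    return rhs_from_fluxes(fluxes(state, env, config))


def rhs_raw(y: np.ndarray, env: Environment, config: ModelConfig) -> np.ndarray:
    """rhs on a bare array, clipping tiny negative excursions to zero.

    Used by integrators and root solvers whose iterates may step slightly
    outside the positive orthant.
    """
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    state = MetaboliteState(**dict(zip(SPECIES, map(float, y))))
    return rhs_from_fluxes(fluxes(state, env, config))


def flux_balance_residuals(solution_state: MetaboliteState, env: Environment,
                           config: ModelConfig) -> dict[str, float]:
    """Relative steady-state flux-balance mismatches.

    At a steady state the upper-glycolysis rates coincide
    (GLUT = HK = PGI = PFK = ALDO, net PFKFB = 0), lower glycolysis carries
    twice that flux (GAPDH = 2 PFK = PK), and PK balances the three pyruvate
    sinks.  Returns each mismatch normalized by the flux magnitude.
    """
    v = fluxes(solution_state, env, config)
    j = v["PFK"]
    scale = max(abs(j), 1e-12)
    return {
        "GLUT=HK": (v["GLUT"] - v["HK"]) / scale,
        "HK=PGI": (v["HK"] - v["PGI"]) / scale,
        "PGI=PFK": (v["PGI"] - v["PFK"]) / scale,
        "PFK=ALDO": (v["PFK"] - v["ALDO"]) / scale,
        "PFKFB_net": v["PFKFB"] / scale,
        "GAPDH=2PFK": (v["GAPDH"] - 2.0 * j) / scale,
        "PK=GAPDH": (v["PK"] - v["GAPDH"]) / scale,
        "PK=sinks": (v["PK"] - v["LDH"] - v["MCT_MITO"] - v["ALA_SINK"]) / scale,
    }


assert len(SPECIES) == N_SPECIES == 12
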