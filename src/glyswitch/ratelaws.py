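"""Enzyme rate laws for the glycolysis model.

Every rate is returned in mM/h.  Allosteric enzymes (PFK, PK, PFKFB) use
MWC/Hill-style laws in which activators relax and inhibitors raise an
allosteric tension factor; the near-equilibrium chain enzymes use reversible
Michaelis-Menten forms whose net rate vanishes exactly at thermodynamic
equilibrium.  The laws were chosen to be analytically invertible in their
substrate wherever the steady-state flux reduction needs it.

Scale constants that are not pinned by reported isozyme data were calibrated
once against the F6P-node switch concentrations (see the methods note) and
are frozen in :class:`ChainParams` and the isozyme catalog defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError, DomainError
from .isozymes import PFKFBIsozyme, PFKIsozyme, PKIsozyme


def _check_nonneg(**concs: float) -> None:
    for name, value in concs.items():
        if value < 0:
            raise DomainError(f"concentration {name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class ChainParams:
    """Kinetic constants of the non-allosteric chain reactions.

    ``v_*`` are reference maximal rates (mM/h at enzyme level 1.0), ``k_*``
    half-saturations (mM) and ``q_*``/``keq_*`` equilibrium constants in the
    glycolytic direction.  Defaults are the calibrated reference set for a
    proliferative mammalian cell.
    """

    # glucose transport (facilitated, symmetric carrier)
    v_glut: float = 1800.0
    k_glut: float = 4.0
    # hexokinase
    v_hk: float = 1180.0
    km_hk_glc: float = 8.0
    km_hk_atp: float = 0.5
    ki_hk_g6p: float = 0.26
    h_hk_g6p: float = 4.0
    # phosphoglucose isomerase (reversible)
    v_pgi: float = 3000.0
    k_pgi: float = 0.4
    q_pgi: float = 0.3          # [F6P]/[G6P] at equilibrium
    # aldolase (reversible)
    v_aldo: float = 4400.0
    k_aldo: float = 400.0
    keq_aldo: float = 0.1       # mM, [DHAP][GAP]/[F16BP] at equilibrium
    # triose phosphate isomerase (reversible)
    v_tpi: float = 5000.0
    k_tpi: float = 1.0
    q_tpi: float = 0.045        # [GAP]/[DHAP] at equilibrium
    # GAPDH (reversible, NAD-dependent)
    v_gapdh: float = 4000.0
    km_gapdh_gap: float = 0.1
    km_gapdh_nad: float = 0.1
    keq_gapdh: float = 0.1      # ([BPG13][NADH])/([GAP][NAD]) at equilibrium
    # phosphoglycerate kinase (reversible)
    v_pgk: float = 4000.0
    km_pgk_bpg: float = 0.05
    km_pgk_adp: float = 0.3
    keq_pgk: float = 1800.0
    # phosphoglycerate mutase (reversible)
    v_pgam: float = 3000.0
    k_pgam: float = 0.5
    q_pgam: float = 0.18        # [PG2]/[PG3] at equilibrium
    # enolase (reversible)
    v_eno: float = 3000.0
    k_eno: float = 0.5
    q_eno: float = 4.0          # [PEP]/[PG2] at equilibrium
    # pyruvate kinase reference Vmax (isoform constants in PKIsozyme)
    v_pk: float = 1000.0
    # lactate dehydrogenase (reversible, strongly poised toward lactate;
    # mildly cooperative in pyruvate so the mitochondrial carrier wins the
    # competition for pyruvate at low flux)
    v_ldh: float = 700.0
    km_ldh_pyr: float = 2.0
    km_ldh_nadh: float = 0.05
    keq_ldh: float = 16000.0    # ([LAC][NAD])/([PYR][NADH]) at equilibrium
    # mitochondrial pyruvate carrier (facilitated, symmetric)
    v_mito: float = 120.0
    k_mito: float = 3.0
    # alanine-linked pyruvate exchange (transaminase-like, near-equilibrium)
    v_ala: float = 20.0
    k_ala: float = 1.0
    q_ala: float = 10.0         # [ALA]/[PYR] at equilibrium
    # PFK reference Vmax (allosteric constants in PFKIsozyme)
    v_pfk: float = 1968.88

    def replace(self, **changes) -> "ChainParams":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# allosteric enzymes
# ---------------------------------------------------------------------------

def rate_pfk(f6p: float, atp: float, f16bp: float, f26bp: float, amp: float,
             iso: PFKIsozyme, level: float = 1.0, v_max: float = 1000.0) -> float:
    """Phosphofructokinase rate (mM/h).

    Hill substrate term in F6P times the fraction of enzyme in the active
    conformation, 1/(1+L).  ATP raises the allosteric tension L; F26BP, AMP
    and (for PFKM/PFKL only) F16BP relax it.  The F16BP factor is omitted
    structurally for isoforms without feedback activation.
    """
    _check_nonneg(F6P=f6p, ATP=atp, F16BP=f16bp, F26BP=f26bp, AMP=amp)
    s = f6p ** iso.h_f6p
    sat = s / (iso.km_f6p ** iso.h_f6p + s)
    relax = (1.0 + f26bp / iso.ka_f26bp) ** iso.h_f26bp
    relax *= (1.0 + amp / iso.ka_amp) ** iso.h_amp
    if iso.ka_f16bp is not None:
        relax *= (1.0 + f16bp / iso.ka_f16bp) ** iso.h_f16bp
    tension = iso.l0 * (atp / iso.ki_atp) ** iso.h_atp / relax
    return level * v_max * sat / (1.0 + tension)


def mixture_rate_pfk(fractions: dict[str, float], f6p: float, atp: float,
                     f16bp: float, f26bp: float, amp: float,
                     catalog: dict[str, PFKIsozyme], level: float = 1.0,
                     v_max: float = 1000.0, tol: float = 1e-9) -> float:
    """Rate of a PFK isoform mixture with the total enzyme level conserved.

    ``fractions`` maps isoform name to its weight; weights must be
    nonnegative and sum to one so that the summed level equals ``level``.
    """
    total = sum(fractions.values())
    if abs(total - 1.0) > tol:
        raise ConfigurationError(f"PFK mixture weights must sum to 1, got {total!r}")
    rate = 0.0
    for name, weight in fractions.items():
        if weight < 0:
            raise ConfigurationError(f"PFK mixture weight for {name} must be >= 0")
        if name not in catalog:
            raise ConfigurationError(
                f"unknown PFK isoform {name!r}; valid: {sorted(catalog)}")
        if weight > 0:
            rate += weight * rate_pfk(f6p, atp, f16bp, f26bp, amp,
                                      catalog[name], level=level, v_max=v_max)
    return rate


def rate_pk(pep: float, adp: float, f16bp: float, atp: float, pyr: float,
            iso: PKIsozyme, level: float = 1.0, v_max: float = 1200.0) -> float:
    """Pyruvate kinase rate (mM/h).

    Hill term in PEP with an apparent Km raised by ATP and lowered by F16BP
    (feed-forward activation, absent in PKM1), an ADP substrate term, and
    competitive product inhibition by cytosolic pyruvate.
    """
    _check_nonneg(PEP=pep, ADP=adp, F16BP=f16bp, ATP=atp, PYR=pyr)
    km_app = iso.km_pep * (1.0 + atp / iso.ki_atp)
    if iso.ka_f16bp is not None:
        km_app /= 1.0 + f16bp / iso.ka_f16bp
    p = pep ** iso.h_pep
    sat = p / (km_app ** iso.h_pep + p)
    return (level * v_max * sat * (adp / (iso.km_adp + adp))
            / (1.0 + pyr / iso.ki_pyr))


def pk_invert_pep(v: float, adp: float, f16bp: float, atp: float, pyr: float,
                  iso: PKIsozyme, level: float = 1.0, v_max: float = 1200.0) -> float:
    """PEP concentration at which PK runs at rate ``v`` (NaN if infeasible)."""
    cap = level * v_max * (adp / (iso.km_adp + adp)) / (1.0 + pyr / iso.ki_pyr)
    if v <= 0 or v >= cap:
        return float("nan")
    km_app = iso.km_pep * (1.0 + atp / iso.ki_atp)
    if iso.ka_f16bp is not None:
        km_app /= 1.0 + f16bp / iso.ka_f16bp
    x = v / cap
    return km_app * (x / (1.0 - x)) ** (1.0 / iso.h_pep)


def rate_pfkfb_kinase(f6p: float, atp: float, pep: float, iso: PFKFBIsozyme,
                      level: float = 1.0) -> float:
    """6-phosphofructo-2-kinase (F26BP synthesis) rate, mM/h."""
    _check_nonneg(F6P=f6p, ATP=atp, PEP=pep)
    u = (f6p / (iso.km_f6p + f6p)) * (atp / (iso.km_atp + atp))
    u /= 1.0 + (pep / iso.ki_pep) ** iso.h_pep
    return level * iso.kp_ratio * iso.vref_phos * iso.f26bp_scale * u


def rate_pfkfb_phosphatase(f26bp: float, iso: PFKFBIsozyme, level: float = 1.0) -> float:
    """Fructose-2,6-bisphosphatase (F26BP hydrolysis) rate, mM/h.

    The phosphatase operates far below its half-saturation at physiological
    F26BP, so a first-order law is used; its rate constant carries the
    expression level so that level scales both domains equally.
    """
    _check_nonneg(F26BP=f26bp)
    return level * iso.vref_phos * f26bp


def rate_pfkfb_net(f6p: float, atp: float, f26bp: float, pep: float,
                   iso: PFKFBIsozyme, level: float = 1.0) -> float:
    """Net F26BP production rate (kinase minus phosphatase), mM/h."""
    return (rate_pfkfb_kinase(f6p, atp, pep, iso, level)
            - rate_pfkfb_phosphatase(f26bp, iso, level))


def pfkfb_f26bp_star(f6p: float, atp: float, pep: float, iso: PFKFBIsozyme) -> float:
    """Steady-state F26BP (the internal zero of the net PFKFB rate, mM).

    Independent of the PFKFB expression level: level scales kinase and
    phosphatase identically, so it cancels from the balance.
    """
    _check_nonneg(F6P=f6p, ATP=atp, PEP=pep)
    u = (f6p / (iso.km_f6p + f6p)) * (atp / (iso.km_atp + atp))
    u /= 1.0 + (pep / iso.ki_pep) ** iso.h_pep
    return iso.kp_ratio * iso.f26bp_scale * u


# ---------------------------------------------------------------------------
# chain enzymes (reversible Michaelis-Menten forms, analytically invertible)
# ---------------------------------------------------------------------------

def rate_glut(glc_ext: float, glc_in: float, p: ChainParams, level: float = 1.0) -> float:
    """Facilitated glucose transport (symmetric carrier), mM/h."""
    _check_nonneg(GLC_EXT=glc_ext, GLC=glc_in)
    return level * p.v_glut * (glc_ext / (p.k_glut + glc_ext)
                               - glc_in / (p.k_glut + glc_in))


def glut_invert_internal(v: float, glc_ext: float, p: ChainParams, level: float = 1.0) -> float:
    """Internal glucose sustaining transport rate ``v`` (NaN if infeasible)."""
    a = glc_ext / (p.k_glut + glc_ext) - v / (level * p.v_glut)
    if a <= 0 or a >= 1:
        return float("nan") if a >= 1 else (float("nan") if v > 0 else 0.0)
    return p.k_glut * a / (1.0 - a)


def rate_hk(glc_in: float, atp: float, g6p: float, p: ChainParams, level: float = 1.0) -> float:
    """Hexokinase rate with G6P feedback inhibition, mM/h."""
    _check_nonneg(GLC=glc_in, ATP=atp, G6P=g6p)
    sat = (glc_in / (p.km_hk_glc + glc_in)) * (atp / (p.km_hk_atp + atp))
    return level * p.v_hk * sat / (1.0 + (g6p / p.ki_hk_g6p) ** p.h_hk_g6p)


def hk_invert_g6p(v: float, glc_in: float, atp: float, p: ChainParams, level: float = 1.0) -> float:
    """G6P level at which HK runs at rate ``v`` (NaN if infeasible)."""
    cap = level * p.v_hk * (glc_in / (p.km_hk_glc + glc_in)) * (atp / (p.km_hk_atp + atp))
    if v <= 0 or v >= cap:
        return float("nan")
    return p.ki_hk_g6p * (cap / v - 1.0) ** (1.0 / p.h_hk_g6p)


def rate_pgi(g6p: float, f6p: float, p: ChainParams, level: float = 1.0) -> float:
    """Reversible phosphoglucose isomerase, mM/h."""
    _check_nonneg(G6P=g6p, F6P=f6p)
    return level * p.v_pgi * (g6p - f6p / p.q_pgi) / (p.k_pgi + g6p + f6p)


def pgi_invert_g6p(v: float, f6p: float, p: ChainParams, level: float = 1.0) -> float:
    vm = level * p.v_pgi
    if vm <= v:
        return float("nan")
    g6p = (v * (p.k_pgi + f6p) + vm * f6p / p.q_pgi) / (vm - v)
    return g6p if g6p >= 0 else float("nan")


def rate_aldo(f16bp: float, dhap: float, gap: float, p: ChainParams, level: float = 1.0) -> float:
    """Reversible aldolase, mM/h."""
    _check_nonneg(F16BP=f16bp, DHAP=dhap, GAP=gap)
    return (level * p.v_aldo * (f16bp - dhap * gap / p.keq_aldo)
            / (p.k_aldo + f16bp + dhap + gap))


def aldo_invert_f16bp(v: float, dhap: float, gap: float, p: ChainParams, level: float = 1.0) -> float:
    vm = level * p.v_aldo
    if vm <= v:
        return float("nan")
    f16bp = (v * (p.k_aldo + dhap + gap) + vm * dhap * gap / p.keq_aldo) / (vm - v)
    return f16bp if f16bp >= 0 else float("nan")


def rate_tpi(dhap: float, gap: float, p: ChainParams, level: float = 1.0) -> float:
    """Reversible triose phosphate isomerase (DHAP -> GAP positive), mM/h."""
    _check_nonneg(DHAP=dhap, GAP=gap)
    return level * p.v_tpi * (dhap - gap / p.q_tpi) / (p.k_tpi + dhap + gap)


def tpi_invert_dhap(v: float, gap: float, p: ChainParams, level: float = 1.0) -> float:
    vm = level * p.v_tpi
    if vm <= v:
        return float("nan")
    dhap = (v * (p.k_tpi + gap) + vm * gap / p.q_tpi) / (vm - v)
    return dhap if dhap >= 0 else float("nan")


def rate_gapdh(gap: float, bpg13: float, nad: float, nadh: float,
               p: ChainParams, level: float = 1.0) -> float:
    """Reversible NAD-dependent GAPDH, mM/h."""
    _check_nonneg(GAP=gap, BPG13=bpg13, NAD=nad, NADH=nadh)
    num = gap * nad - bpg13 * nadh / p.keq_gapdh
    den = (p.km_gapdh_gap + gap) * (p.km_gapdh_nad + nad)
    return level * p.v_gapdh * num / den


def gapdh_invert_gap(v: float, bpg13: float, nad: float, nadh: float,
                     p: ChainParams, level: float = 1.0) -> float:
    vm = level * p.v_gapdh
    c = bpg13 * nadh / p.keq_gapdh
    denom = vm * nad - v * (p.km_gapdh_nad + nad)
    if denom <= 0:
        return float("nan")
    gap = (v * p.km_gapdh_gap * (p.km_gapdh_nad + nad) + vm * c) / denom
    return gap if gap >= 0 else float("nan")


def rate_pgk(bpg13: float, pg3: float, adp: float, atp: float,
             p: ChainParams, level: float = 1.0) -> float:
    """Reversible phosphoglycerate kinase, mM/h."""
    _check_nonneg(BPG13=bpg13, PG3=pg3, ADP=adp, ATP=atp)
    num = bpg13 * adp - pg3 * atp / p.keq_pgk
    den = (p.km_pgk_bpg + bpg13) * (p.km_pgk_adp + adp)
    return level * p.v_pgk * num / den


def pgk_invert_bpg(v: float, pg3: float, adp: float, atp: float,
                   p: ChainParams, level: float = 1.0) -> float:
    vm = level * p.v_pgk
    c = pg3 * atp / p.keq_pgk
    denom = vm * adp - v * (p.km_pgk_adp + adp)
    if denom <= 0:
        return float("nan")
    bpg = (v * p.km_pgk_bpg * (p.km_pgk_adp + adp) + vm * c) / denom
    return bpg if bpg >= 0 else float("nan")


def rate_pgam(pg3: float, pg2: float, p: ChainParams, level: float = 1.0) -> float:
    """Reversible phosphoglycerate mutase, mM/h."""
    _check_nonneg(PG3=pg3, PG2=pg2)
    return level * p.v_pgam * (pg3 - pg2 / p.q_pgam) / (p.k_pgam + pg3 + pg2)


def pgam_invert_pg3(v: float, pg2: float, p: ChainParams, level: float = 1.0) -> float:
    vm = level * p.v_pgam
    if vm <= v:
        return float("nan")
    pg3 = (v * (p.k_pgam + pg2) + vm * pg2 / p.q_pgam) / (vm - v)
    return pg3 if pg3 >= 0 else float("nan")


def rate_eno(pg2: float, pep: float, p: ChainParams, level: float = 1.0) -> float:
    """Reversible enolase, mM/h."""
    _check_nonneg(PG2=pg2, PEP=pep)
    return level * p.v_eno * (pg2 - pep / p.q_eno) / (p.k_eno + pg2 + pep)


def eno_invert_pg2(v: float, pep: float, p: ChainParams, level: float = 1.0) -> float:
    vm = level * p.v_eno
    if vm <= v:
        return float("nan")
    pg2 = (v * (p.k_eno + pep) + vm * pep / p.q_eno) / (vm - v)
    return pg2 if pg2 >= 0 else float("nan")


def rate_ldh(pyr: float, nad: float, nadh: float, lac: float,
             p: ChainParams, level: float = 1.0) -> float:
    """Reversible lactate dehydrogenase (pyruvate -> lactate positive), mM/h.

    Carries a second pyruvate factor in the saturation denominator (mild
    cooperativity of the tetramer), which keeps LDH a minor pyruvate sink at
    the low-flux state where the mitochondrial carrier dominates; the net
    rate still vanishes exactly at the mass-action equilibrium.
    """
    _check_nonneg(PYR=pyr, NAD=nad, NADH=nadh, LAC=lac)
    num = pyr * (pyr * nadh - lac * nad / p.keq_ldh)
    den = (p.km_ldh_pyr ** 2 + pyr ** 2) * (p.km_ldh_nadh + nadh)
    return level * p.v_ldh * num / den


def rate_mito(pyr: float, pyr_m: float, p: ChainParams, level: float = 1.0) -> float:
    """Mitochondrial pyruvate carrier (symmetric facilitated transport), mM/h."""
    _check_nonneg(PYR=pyr, PYR_M=pyr_m)
    return level * p.v_mito * (pyr / (p.k_mito + pyr) - pyr_m / (p.k_mito + pyr_m))


def rate_ala_sink(pyr: float, ala: float, p: ChainParams, level: float = 1.0) -> float:
    """Alanine-linked pyruvate exchange (transaminase-like, reversible), mM/h."""
    _check_nonneg(PYR=pyr, ALA=ala)
    return level * p.v_ala * (pyr - ala / p.q_ala) / (p.k_ala + pyr + ala)
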