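# glyswitch default model configuration (HeLa-like proliferative cell).
#
# Provenance of the constants:
#   * Isozyme-discriminating allosteric constants are reported experimental
#     values for mammalian isozymes: PFK F16BP activation constants
#     (PFKM 0.35 mM, PFKL 0.65 mM; PFKP carries no F16BP activation), PK
#     PEP Km / ATP Ki / F16BP Ka per isoform (PKL 0.6/0.05/0.01, PKR
#     1.2/0.12/0.04, PKM1 0.08/2.5/none, PKM2 0.4/3.5/0.04 mM), and PFKFB
#     tissue K/P activity ratios (liver 1.5-2.5 stored as 2.0, muscle 0.4,
#     heart 1.8, brain/placenta 3.1, inducible/tumor 710, testis 4.1).
#   * All remaining shape and scale constants (allosteric tension l0, Hill
#     orders, effector constants for F26BP/AMP/PEP, chain Vmax and Km
#     values) are calibrated: the two-enzyme F6P node (PFK + aldolase,
#     DHAP 0.04 / GAP 0.02 mM) reproduces switch-down/switch-up at
#     0.09 / 0.30 mM F6P, and the full pathway reproduces the qualitative
#     isozyme-dependent mono/bistability patterns.  See docs/methods.md.
#   * Environment concentrations are standard cytosolic literature values;
#     mitochondrial pyruvate is fixed at 0.1 mM.
#   * This default selects PFKL + PKM2 (both regulatory loops active) at
#     K/P = 10 with a reduced glucose-transport level (0.12) representing
#     transport-limited cultured cells; its bistable glucose window
#     brackets 2-4.5 mM with switch-down just above 0.6 mM.
allosteric_constants:
  pfk:
    PFKL:
      h_amp: 2.0
      h_atp: 2.0
      h_f16bp: 4.0
      h_f26bp: 4.0
      h_f6p: 4.0
      ka_amp: 0.1
      ka_f16bp: 0.65
      ka_f26bp: 0.012
      ki_atp: 1.0
      km_f6p: 0.201336
      l0: 1000.0
      name: PFKL
    PFKM:
      h_amp: 2.0
      h_atp: 2.0
      h_f16bp: 4.0
      h_f26bp: 4.0
      h_f6p: 4.0
      ka_amp: 0.1
      ka_f16bp: 0.35
      ka_f26bp: 0.012
      ki_atp: 1.0
      km_f6p: 0.201336
      l0: 1000.0
      name: PFKM
    PFKP:
      h_amp: 2.0
      h_atp: 2.0
      h_f16bp: 4.0
      h_f26bp: 4.0
      h_f6p: 4.0
      ka_amp: 0.1
      ka_f16bp: null
      ka_f26bp: 0.012
      ki_atp: 1.0
      km_f6p: 0.201336
      l0: 1000.0
      name: PFKP
  pk:
    PKL:
      h_pep: 4.0
      ka_f16bp: 0.01
      ki_atp: 0.05
      ki_pyr: 6.0
      km_adp: 0.3
      km_pep: 0.6
      name: PKL
    PKM1:
      h_pep: 4.0
      ka_f16bp: null
      ki_atp: 2.5
      ki_pyr: 6.0
      km_adp: 0.3
      km_pep: 0.08
      name: PKM1
    PKM2:
      h_pep: 4.0
      ka_f16bp: 0.04
      ki_atp: 3.5
      ki_pyr: 6.0
      km_adp: 0.3
      km_pep: 0.4
      name: PKM2
    PKR:
      h_pep: 4.0
      ka_f16bp: 0.04
      ki_atp: 0.12
      ki_pyr: 6.0
      km_adp: 0.3
      km_pep: 1.2
      name: PKR
chain:
  h_hk_g6p: 4.0
  k_ala: 1.0
  k_aldo: 400.0
  k_eno: 0.5
  k_glut: 4.0
  k_mito: 3.0
  k_pgam: 0.5
  k_pgi: 0.4
  k_tpi: 1.0
  keq_aldo: 0.1
  keq_gapdh: 0.1
  keq_ldh: 16000.0
  keq_pgk: 1800.0
  ki_hk_g6p: 0.26
  km_gapdh_gap: 0.1
  km_gapdh_nad: 0.1
  km_hk_atp: 0.5
  km_hk_glc: 8.0
  km_ldh_nadh: 0.05
  km_ldh_pyr: 2.0
  km_pgk_adp: 0.3
  km_pgk_bpg: 0.05
  q_ala: 10.0
  q_eno: 4.0
  q_pgam: 0.18
  q_pgi: 0.3
  q_tpi: 0.045
  v_ala: 20.0
  v_aldo: 4400.0
  v_eno: 3000.0
  v_gapdh: 4000.0
  v_glut: 1800.0
  v_hk: 1180.0
  v_ldh: 700.0
  v_mito: 120.0
  v_pfk: 1968.88
  v_pgam: 3000.0
  v_pgi: 3000.0
  v_pgk: 4000.0
  v_pk: 1000.0
  v_tpi: 5000.0
environment:
  ADP: 0.5
  ALA: 0.5
  AMP: 0.1
  ATP: 3.0
  CA: 0.0001
  GLC_EXT: 5.0
  K: 140.0
  LAC: 1.8
  MG: 0.8
  NAD: 0.6
  NADH: 0.06
  PEP_NODE: 0.008
  PYR_M: 0.1
enzyme_levels:
  ALA_SINK: 1.0
  ALDO: 1.0
  ENO: 1.0
  GAPDH: 1.0
  GLUT: 0.12
  HK: 1.0
  LDH: 1.0
  MCT_MITO: 1.0
  PFK: 1.0
  PFKFB: 1.0
  PGAM: 1.0
  PGI: 1.0
  PGK: 1.0
  PK: 1.0
  TPI: 1.0
isozymes:
  pfk_fractions:
    PFKL: 1.0
  pfkfb:
    f26bp_scale: 0.008
    h_pep: 4.0
    ki_pep: 0.007
    km_atp: 0.5
    km_f6p: 0.03
    kp_range: null
    kp_ratio: 10.0
    name: PFKFB_custom
    vref_phos: 4.5
  pk: PKM2
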