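# Methods

## The model

`glyswitch` implements a mechanistic ordinary-differential-equation model of
mammalian glycolysis from glucose uptake to the three cytosolic pyruvate
sinks (lactate dehydrogenase, mitochondrial pyruvate transport, and an
alanine-linked transaminase exchange).  Twelve intermediates are balanced:
intracellular glucose, G6P, F6P, F16BP, F26BP, DHAP, GAP, 1,3-BPG, 3-PG,
2-PG, PEP and cytosolic pyruvate.  Energy nucleotides (ATP/ADP/AMP), the
redox pair (NAD+/NADH), ions, mitochondrial pyruvate, extracellular lactate
and alanine are held fixed (an `Environment`), insulating the glycolytic
balance from the rest of metabolism.  Units are mM, mM/h and hours
throughout; cell-specific rates (mmol per 10^9 cells per h) are obtained
with a fixed cytosolic-volume conversion of 3.66e-3 L per 10^9 cells,
chosen so the high-flux state of the default configuration matches the
uptake scale measured in proliferating cultured cells (~0.31 mmol/10^9
cells/h).

The biology under study is the switch structure created by two positive
regulatory loops:

* **Loop 1** - feedback activation of phosphofructokinase by its product
  F16BP (present in PFKM and PFKL, structurally absent in PFKP), plus
  F26BP activation of PFK.
* **Loop 2** - feed-forward activation of pyruvate kinase by F16BP
  (PKM2/PKL/PKR, absent in PKM1), PEP feedback inhibition of the PFKFB
  kinase domain, and F26BP activation of PFK.  Active together these form
  a second positive loop through the lower pathway.

Which loops operate is purely a question of which isozymes a configuration
selects; absence of a regulation is always structural (the corresponding
factor is omitted from the rate law), never a large-constant limit.

## Rate laws

The exact mechanistic rate equations this model family descends from are
not part of this package's inputs, so the laws here are authored
MWC/Hill-style structures whose unpinned constants were calibrated (see
below).  The forms:

* **PFK**: `v = V * s(F6P) / (1 + L)` with a Hill-4 substrate term and an
  allosteric tension `L = l0 (ATP/KiATP)^2 / [(1+F16BP/Ka16)^4
  (1+F26BP/Ka26)^4 (1+AMP/KaAMP)^2]`.  Activators relax the tension (shift
  toward the active conformation); ATP raises it.  The F16BP factor exists
  only for PFKM/PFKL, with the isoform-specific activation constants 0.35
  and 0.65 mM.
* **PK**: Hill-4 in PEP with an apparent Km raised by ATP
  (`Km (1+ATP/Ki)`) and divided by `(1+F16BP/Ka)` for the activatable
  isoforms; an ADP substrate term; competitive product inhibition by
  pyruvate (Ki 6 mM).  Isoform PEP Km / ATP Ki / F16BP Ka values are the
  reported ones (PKL 0.6/0.05/0.01, PKR 1.2/0.12/0.04, PKM1 0.08/2.5/none,
  PKM2 0.4/3.5/0.04 mM).
* **PFKFB**: a Michaelis-Menten kinase domain (Km F6P 0.03 mM, Km ATP
  0.5 mM) with Hill-4 PEP inhibition (Ki 0.007 mM) against a first-order
  phosphatase (the phosphatase operates far below saturation at
  physiological F26BP).  The K/P activity ratio multiplies the kinase
  maximal rate; the expression level multiplies both domains, so the F26BP
  set point `F26BP* = f26bp_scale * (K/P) * u(F6P, ATP, PEP)` depends on
  K/P but provably not on the level.  The phosphatase rate constant
  (4.5/h at level 1) is the single purely dynamical dial: it sets the
  F26BP relaxation time without touching any steady state.
* **Chain enzymes** (GLUT, HK, PGI, ALDO, TPI, GAPDH, PGK, PGAM, ENO, LDH,
  mitochondrial carrier, alanine exchange): reversible Michaelis-Menten
  forms whose net rate vanishes exactly at thermodynamic equilibrium, with
  HK carrying the always-active G6P feedback inhibition (Hill 4, Ki
  0.26 mM).  LDH carries a second pyruvate factor (mild tetramer
  cooperativity) so that the mitochondrial carrier out-competes it for
  pyruvate at the low-flux state: the low state is oxidative (most
  pyruvate to mitochondria) and the high state lactogenic, which keeps the
  lactate-to-glucose flux ratio within its stoichiometric bound of 2 and
  higher on the high branch than on the low branch.  The forms were chosen
  to be analytically invertible in their substrate, which the steady-state
  reduction (below) exploits.

## Calibration

Constants not pinned by isozyme data were calibrated in two stages and then
frozen:

1. **F6P-node anchor.**  The two-enzyme node (PFK + aldolase, trioses fixed
   at DHAP 0.04 / GAP 0.02 mM, PFKL) is required to place its switch-down /
   switch-up concentrations at 0.09 and 0.30 mM F6P.  For a given shape
   (l0, aldolase operating regime) the fold loads determine the PFK
   substrate Km and Vmax in closed form; the shape itself (l0 = 1000,
   aldolase in its near-linear regime) was selected so that the high-flux
   branch exists throughout the plotted F6P range and the full model
   retains enough activation gain.
2. **Pathway patterns.**  Supply-side constants (GLUT/HK) and the
   PFKFB coupling were tuned so that the four canonical isozyme sets
   reproduce their qualitative diagrams: PFKP+PKM1 monostable saturating;
   PFKL+PKM1 bistable (window ~1.2-19 mM glucose); PFKP+PKM2 bistable at
   higher glucose (window starting ~3.9 mM, extending past 25 mM);
   PFKL+PKM2 multistable with a window from below 1 mM to ~9.3 mM.  The node anchors and the K/P-loss threshold of
   the three-enzyme node (bistable up to K/P ~12, lost by 15) were held
   fixed during this stage.

Two reported structural features are **not** attainable in this rate-law
family and the corresponding tests are deliberately left failing: a window
with three stable plus two unstable states for PFKL+PKM2 at K/P = 10, and
five coexisting states at high NAD/NADH.  The reason is geometric: Loop 2's
fold is created by PEP falling through the kinase inhibition constant,
which here happens at fluxes where F16BP has already saturated Loop 1's
activation, so the two folds merge into a single bistable structure
instead of nesting.  Separating them would require the PEP crossing to
occur above Loop 1's upper fold flux, which would simultaneously destroy
the Loop-2-only (PFKP+PKM2) bistability.

## Steady states

Two independent routes:

* **Scalar flux reduction** (exhaustive).  At steady state every
  intermediate follows from the upper-glycolysis flux J by analytic
  inversion of the chain laws (pyruvate from the sink balance, PEP from
  the PK balance with the lower chain slaved to it, F6P from the PFK
  balance with F26BP at its PFKFB zero, then G6P and internal glucose).
  The remaining hexokinase balance R(J) is scanned on a dense flux grid
  (sign changes bracketed by Brent's method; infeasibility boundaries
  bisected), enumerating *all* steady states including unstable ones.
* **Multistart** (the classical recipe).  Pseudorandom initial guesses
  (log-uniform over 1e-4..10 mM per species by default; a standard-uniform
  mode is available) are relaxed briefly along the flow and polished by a
  Newton-type solver.  Because Newton iterations do not converge from
  arbitrary states of this stiff system, the pre-relaxation step is
  essential; it means the multistart route recovers the stable states,
  while saddles enter through the reduction.  The two routes cross-check
  each other in the test suite.

Accepted roots must satisfy max |d/dt| < 1e-8 mM/h; duplicates are merged
at 1e-4 relative tolerance keeping the lowest-residual representative.
Stability comes from the eigenvalues of a central finite-difference
Jacobian (relative step 1e-6): stable iff every real part is below -1e-9/h,
with a "marginal" label in between that scans treat as unresolved.

## Scans, dynamics and experiments

Bifurcation scans enumerate the full steady-state set per grid point
(per-point seeds derived from a master seed) and refine switch points by
bisection on the coexisting-state count.  Hysteresis paths follow branches
by nearest-neighbour continuation in log-concentration space.  Transient
runs use LSODA at rtol 1e-8 / atol 1e-10 with piecewise-constant glucose
inputs integrated segment by segment; 500 h is the default settling
horizon.  The glucose-pulse protocol starts on the algebraic low-flux root
(determinism), pulses at t0 = 50 h for 1.5 h, and classifies the outcome
by the branch the trajectory settles on.  The default pulse amplitude is
25 mM — the high-glucose culture concentration — because commitment is
bottlenecked by the slow passage past the saddle-node ghost just above
switch-up, and a pulse barely above switch-up cannot discriminate PFKFB
levels within 1.5 h at any phosphatase rate.

The cultured-cell hysteresis analogue preconditions the system for 12 h at
0.6 or 25 mM glucose (starting from the high-glucose state, as for cells
taken from stock culture), then assays 6 h at each test concentration and
reports the quasi-steady uptake and lactate fluxes.  The default
"HeLa-like" configuration is PFKL+PKM2 at K/P = 10 with the glucose
transporter at 12% of the reference level (transport-limited uptake, as
for cells in culture); this places switch-down just above 0.6 mM and
switch-up just below 10 mM, so the protocol is history-dependent exactly
at 2, 3 and 4.5 mM and history-independent at 0.6 and 25 mM.

## Synthetic fixtures

The toy bistable system `dx/dt = b x^n/(K^n + x^n) + a - c x` shares the
feedback-activation-versus-linear-removal geometry of the F6P node; its
steady states are roots of a degree-(n+1) polynomial with stability from
the scalar derivative, giving an exactly solvable oracle for the
multistart/scanning machinery (folds, near-tangent branches included).
Randomized configurations perturb each enzyme level by 10^u, u uniform in
±1 decade.  What these fixtures do *not* emulate: measurement noise,
cell-to-cell heterogeneity, or the transcriptome-derived co-variation of
enzyme levels in real tissues — passing tests certify the solvers and the
model's internal consistency, not agreement with any particular cell line.

## Numerical choices and limitations

* Multistart default n_starts = 200; residual bound 1e-8 mM/h; dedupe
  tolerance 1e-4; stability margin 1e-9/h; these were fixed once against
  the toy-oracle suite.
* The flux-reduction grid uses ~500 points (log-dense at low flux) with
  boundary bisection; nearly tangent fold pairs closer than the refined
  grid could in principle be missed, which the multistart route and the
  count-parity property test guard against.
* Branch tracking uses nearest-neighbour continuation with the dedupe
  tolerance ×10; the quasi-static protocol is the only basin probe —
  exhaustive basin mapping is out of scope.
* F16BP concentrations on the high-flux branch run high (several mM to
  tens of mM) because aldolase operates in its near-linear regime; this is
  the price of anchoring the node switch concentrations while keeping the
  high branch in existence over the full F6P range.
* The model's low/high flux contrast (~30x) exceeds the ~6x measured in
  cultured cells; the cell-volume conversion matches the high-flux scale,
  so low-state specific rates are under-predicted.
* Thermodynamic (Haldane) consistency beyond the transcribed reversible
  forms, pH dependence, and SBML import/export are non-goals.
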