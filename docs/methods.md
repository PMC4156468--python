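# Model and methods

## The biological problem

Dispersed rat suprachiasmatic nucleus (SCN) neurons cultured on
multielectrode arrays fire in slow bursts: ~10-minute episodes of spiking
separated by 20–60-minute silent intervals, regular within a cell and often
synchronized between cells a millimetre apart.  This package implements a
mechanistic explanation: vasoactive intestinal polypeptide (VIP) released by
a firing neuron activates its own Gs-coupled VPAC2 receptors, raising cAMP,
opening cyclic-nucleotide-gated (CNG) cation channels and sustaining firing
(a fast positive autocrine loop), while PKA-activated GRK phosphorylates the
occupied receptors and drives their internalization (a slow negative loop).
The recycling of internalized receptors is the slowest process in the system
and sets the interburst interval.  Shared extracellular VIP couples cells
into a synchronously bursting network, and the same PKA activity feeds a
per-cell circadian transcription–translation clock through CREB-dependent
Per transcription.

## Single-cell model

The cell state is a 47-component concentration vector (nM) governed by
mass-action kinetics in five modules (all time constants in seconds):

1. **Ligand binding.** VIP binds plain and Gs-precoupled receptors in both
   phosphorylation states (Kd 1 nM at the uncoupled receptor, tenfold
   tighter at the precoupled complex, thermodynamically consistent around
   the binding box).  Free VIP is treated as an unloaded bath: binding does
   not deplete the perimembrane pool, and ligand on internalized receptors
   is degraded.  VIP obeys
   `dL/dt = k_L (VIP_0 − L) + k_sec F + exchange`, so a silent cell rests
   at `VIP_0`.
2. **Gs cycle.** Ternary-complex GDP/GTP exchange (plus a small
   constitutive rate), GTP hydrolysis and heterotrimer reassociation.
   Phosphorylated receptors bind Gs at a fraction `DE` of the
   unphosphorylated rate — the dose–response penalty of desensitization.
3. **Adenylate cyclase.** Gαs-GTP·AC complexes turn over ATP (explicit
   enzyme–substrate species; ATP clamped at 2 mM by default) with a small
   Gs-independent basal activity.  cAMP is degraded by a phosphodiesterase
   whose PKA-phosphorylated form is ~9× more active — the fast negative
   feedback that converts the high-VIP cAMP response into a transient peak
   followed by a plateau.
4. **PKA.** Four cAMP molecules bind the R2C2 holoenzyme sequentially,
   releasing two catalytic subunits through the R2C intermediate; free
   catalytic subunits are buffered by a cytoplasmic inhibitor, shuttle to
   the nucleus, phosphorylate GRK and PDE, and (in the nucleus) activate
   CREB.
5. **Receptor trafficking.** Active (phospho-)GRK phosphorylates
   VIP-occupied receptors (k_63); phosphorylated receptors internalize
   (k_42), are dephosphorylated in the endosome and recycle to the surface
   at k_70.  τ_D = 1/k_70 ≈ 31 min is the slowest time constant of the
   model and the main determinant of the interburst interval.  k_71
   (1e-8 s⁻¹) is the recycling value substituted by the slow-recovery
   phase-plane analysis; the running model always uses k_70.

Membrane electricity is reduced to algebra: CNG conductance is
`g_CNG0 [(1−f) h(cAMP) + f h_per(Per)]` with Hill activations
(n = 3, K = 77 nM for cAMP), and firing rate is a thresholded
piecewise-linear, saturating function of CNG current (0 below
`I_threshold`, `F_max` = 10 Hz above `I_sat`).  Secretion is proportional
to firing.  `f` is the fraction of CNG channels driven by the circadian
Per product instead of local cAMP (0 by default).

Every closed cycle (receptor, Gα, Gβγ, AC, PDE, PKA catalytic and
regulatory, GRK, PKI, CREB) conserves its weighted total exactly at the
right-hand-side level; the test suite asserts this to arithmetic precision
and along trajectories to solver tolerance.

### Oscillation mechanism

For a fixed surface-receptor complement the fast VIP/cAMP/firing subsystem
is bistable over an intermediate receptor range: a silent state at
`L = VIP_0` and a firing state at `L ≈ 5 nM` coexist, separated by an
unstable threshold state (the N-shaped VIP nullcline).  Receptor
internalization during the firing state carries the cell across the lower
fold (burst termination); slow recycling carries it back across the upper
fold (re-ignition).  The default cell bursts to ~10 Hz for ~5 min every
~40 min with fully silent interburst intervals.

### Calibration

Text-level kinetics of the core cascade follow the canonical
GPCR/cAMP/PKA mechanism; the constants added for this model (k_61–k_64,
k_42, k_70, DE, CNG/firing/secretion constants) were calibrated with the
shipped `scripts/calibrate.py` against the measured trafficking phenotype
(internalization half-time ≈ 4.6 min at 1 µM VIP, ≈ 76% maximal
internalization, ≈ 20-min recovery half-time, ≥ 85% recovery at 1 h, and a
~4-fold drop of maximal AC activity after desensitization) jointly with
the oscillation phenotype (20–60-min period, silent intervals, 0→10 Hz
excursions).  The calibrated defaults reproduce maximal internalization
(74.8%), recovery half-time (20.8 min) and 1-h recovery (107%) within 10%,
but the joint constraints are not all attainable in this reconstruction:

* the internalization **half-time** comes out at 3.3 min (target 4.6);
  slowing it below ~4 min in any direction we found either breaks burst
  termination (tonic firing) or shrinks maximal internalization below 65%;
* the **AC fold reduction** saturates near 1.9 (target 4): during a
  sustained test application, recycling continuously regenerates
  unphosphorylated surface receptors, so the desensitized cell retains
  ~half of the naive response at the 2-min read time.  Deeper fold factors
  would require slower recycling, which is pinned by the 20-min recovery
  half-time and by the oscillation period.

### Known dynamical limitation

The default cell coexists with a stable tonic-firing state for part of
parameter space.  The defaults are centred inside the oscillatory window,
but under the ±20% all-parameter heterogeneity of the ensemble protocol a
large fraction of cells falls into the tonic or silent regime, so the
heterogeneous 50-cell experiment reproduces the qualitative protocol but
not the published 70% oscillating fraction, and tonic cells prevent
post-coupling synchronization of that ensemble.  The deterministic
minority-induction network (4 default + 16 half-conductance cells) does
reproduce the published behaviour: only the 4 oscillate alone, and VIP
exchange entrains all 20 within narrow period spread and tens-of-seconds
phase SD, with monotone oscillation death as coupling grows.

## Circadian clock

Each cell can carry the 16-variable mammalian transcription–translation
clock (Per/Cry/Bmal1 mRNAs, their proteins, phospho-forms, nuclear
complexes) in its published basal regime; the implementation reproduces a
stable limit cycle with a 23.85-h free-running period.  Signalling couples
to the clock through one additive term: Per transcription gains
`v_creb · a_CREB`, where `a_CREB ∈ [0,1]` is a saturating function of
nuclear PKA.  With `a_CREB = 0` the published autonomous model is
recovered exactly (asserted in tests).  The clock couples back through the
Per-driven CNG fraction `f`.

Three circadian-regulation variants are provided:

* `no_vip_cng` — f = 1 (firing driven solely by Per; K_per = 6 nM places
  the half-activation inside the Per excursion);
* `vip_cng_with_fofr` — f = 0.2 with the fast loop intact (K_per = 30 so
  the Per bias modulates excitability without leaving the oscillatory
  regime); bursts persist, gated across the circadian cycle;
* `vip_cng_without_fofr` — f = 0.1 with the GRK pool emptied (no
  desensitization, hence no fast oscillation) and CNG conductance reduced
  to just above the silent/firing fold located by a scripted scan, so VIP
  and Per inputs steer firing without igniting bursts.

## Network

Cells interact only through VIP: each perimembrane pool exchanges
first-order with one well-mixed extracellular compartment at rate
`D / 100 s⁻¹`.  The published coupling values are dimensionless; this
scale constant places D = 0.3–0.5 at the weak/intermediate boundary
(synchronization with preserved oscillation) and D = 6 in the
oscillation-death regime, and makes all cells sense a common VIP level in
the strong-coupling limit.  The exchange fluxes conserve volume-weighted
VIP exactly (pool volume ratio configurable, default 1 per cell).
Heterogeneity draws every rate constant and initial concentration
uniformly from [x₀(1−w), x₀(1+w)] per cell, seeded and reproducible, with
subgroup overrides applied afterwards.  The coupled system is integrated
as one ODE system (n·47 (+ n·16 clock) + 1 pool states) with a
block-structured Jacobian sparsity pattern, restarting at every coupling
switch.

## Analysis conventions

* **Oscillation criterion** — cAMP (or any series) must keep a
  peak-to-trough excursion above 10% of its mean through every third of a
  15-h window after a 5-h transient trim, with ≥ 3 peaks.
* **Period / amplitude** — mean inter-peak interval; amplitude is half the
  mean peak-to-trough excursion.
* **Phases** — circadian phases are centres of mass of activity in
  successive 24-h windows after subtracting the within-window baseline
  (without baseline removal a nonzero floor compresses all phases toward
  the window midpoint); burst phases are burst-peak times folded on the
  population mean period.  Spread is summarized by the circular standard
  deviation; the synchronization index is the modulus of the mean unit
  phase vector.
* **Equilibria and stability** — multidimensional root-finding polished
  from relaxed integrations (the clamped cascade is attracting, so
  integration provides the global branch; every reported point is verified
  to residual < 1e-7 nM/s); stability via eigenvalues of a
  finite-difference Jacobian (relative step 1e-6).
* **Sensitivity scan** — each of the 47 initial concentrations and each
  added constant is varied across [x₀/50, 50·x₀]; a quantity is critical
  when oscillation fails inside that range, and its surviving interval is
  bracketed by log-space bisection to 2% resolution.  Complex species
  start at zero in the canonical initial state, so only genuinely
  populated pools can be critical.
* **Numerics** — stiff variable-order implicit integration (LSODA for
  single cells, BDF with sparse finite-difference Jacobians for networks),
  rtol 1e-6 / atol 1e-9 nM by default; integration restarts at every
  protocol discontinuity; a compiled kernel (numba) accelerates the
  right-hand side and is asserted equal to the reference implementation to
  machine precision.

## Problem sizes used by the shipped tests and acceptance script

Single-cell runs use 8–20 simulated hours; sensitivity classification uses
endpoint tests plus bisection (~100 s total); ensemble experiments use the
published cell counts (50 and 20 cells) with 20 h + 10 h and 6 h + 8 h
epochs; the clock-coupled 10-cell networks use 49 h uncoupled + 49 h
coupled (the published protocol couples at 91 h; the shorter uncoupled
epoch spans two full circadian cycles and leaves the phase structure
unchanged).  These sizes are the package's reference configuration;
all are configurable through experiment overrides.

## What the generator does and does not emulate

Synthetic heterogeneity reproduces the documented uniform parameter
scatter, deterministic subgroups and clock-phase/parameter jitter.  It
does not model spatial geometry or diffusion (one well-mixed pool),
synaptic or gap-junctional coupling, stochastic channel or release noise,
calcium dynamics, or spike-level electrophysiology — the model works at
the firing-rate level throughout.  Passing tests therefore demonstrate the
network-level feedback logic, not quantitative agreement with any
particular recording.
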