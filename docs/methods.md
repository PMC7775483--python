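# Model and methods

## Scope

`camkii-atria` simulates a single mouse atrial myocyte in which
Ca²⁺/calmodulin-dependent protein kinase II (CaMKII) signaling is coupled
bidirectionally to membrane electrophysiology and intracellular Ca²⁺
cycling.  The package's scientific core is the CaMKII layer — an 8-state
activation/oxidation Markov chain, a 6-fold overexpression remodeling
recipe, and the protocols built on them (steady-state pacing, burst pacing
with DAD detection, ion/phosphorylation clamps, and RyR
threshold/release mapping over the ([Ca²⁺]_SR × RyR-phosphorylation)
plane).  The surrounding electrophysiology is a compact mouse atrial
formulation authored for this package: the literature baselines it emulates
are cited by genre (mouse atrial AP models; dyadic CaMKII signaling
frameworks), but every equation here is re-derived and re-calibrated, so
the quantitative targets are treated as calibration targets with stated
tolerances, not as exact reproductions.

## CaMKII chain

Subunit states: `Pi` (inactive), `Pb` (Ca₄CaM-bound), `Pt`
(autophosphorylated, CaM-trapped), `Pt2` (autophosphorylated, Ca₂CaM),
`Pa` (autonomous), `Pb2` (Ca₂CaM-bound, inactive), plus the oxidation pair
`Pot` (oxidized, Ca₄CaM-bound) and `Po` (oxidized, CaM-free).  Active
states: `Pb, Pt, Pt2, Pa, Pot, Po`, all with 100% activity.

Transitions (rates in s⁻¹, concentrations in µM unless noted):

* `Pi ⇌ Pb`: `k_ib·[Ca₄CaM]` / `k_bi` with `k_bi = 2.2`,
  `k_ib = 2.2/0.0335` (Kd = 33.5 nM).
* `Pi ⇌ Pb2`: `k_ib2·[Ca₂CaM]` / `k_b2i`.
* `Pb ⇌ Pb2`: Ca (de)loading of the bound CaM at `k_cam_ca = 30 s⁻¹`,
  weighted by the N-lobe loading fraction inferred from the local
  Ca₄CaM/Ca₂CaM ratio.  Without this step, bound kinase would outlive the
  Ca transient by ~1/k_bi ≈ 0.5 s and grossly over-autophosphorylate.
* `Pb → Pt`: autophosphorylation at `k_auto·T` where `T` is the active
  fraction (a neighbouring active subunit performs the phosphorylation).
* `Pt → Pa` (trapped-CaM dissociation), `Pa ⇌ Pt2` (Ca₂CaM exchange),
  `Pa + Ca₄CaM → Pt`.
* PP1 dephosphorylates `Pa → Pi` and `Pt2 → Pb2` with Michaelis–Menten
  kinetics **in the absolute substrate concentration**
  `(Pa+Pt2)·[CaMKII]`.  This is the phosphatase-saturation mechanism: at
  6× CaMKII the same phosphatase pool is saturated, so the autonomous
  fraction equilibrates several-fold higher than in wild type.
* Oxidation: `Pb → Pot` at `k_ox·[ROS]/([ROS]+Km_ROS)`; reduction
  `Pot → Pb` and `Po → Pi` at `k_redox·[MsrA]/([MsrA]+Km_MsrA)`;
  `Pot ⇌ Po` exchanges Ca₄CaM with exactly the `Pi ⇌ Pb` rates.
  Autophosphorylated subunits are structurally excluded from oxidation
  (no oxidation transitions out of `Pt/Pt2/Pa`).

Two chain instances run per cell — junctional and bulk-cytosolic — each
driven by its local CaM pools (equilibrium two-lobe model:
`Ca₄CaM = CaM_tot·fC·fN`, `Ca₂CaM = CaM_tot·fC·(1−fN)` with Hill-2 lobes,
`Kd_C = 2 µM`, `Kd_N = 15 µM`).  The junctional pool (120 µM CaMKII in
wild type) is the one reported as "activated CaMKII".

### Oxidation time base

The kinase module ships the dose-response constants
`k_ox = 6.48e-6 s⁻¹`, `Km_ROS = 60 µM`, `k_redox = 0.28 s⁻¹`,
`Km_MsrA = 0.34 mM`, and these are what `fit_oxidation_params` re-derives
from dose-response tables.  At that scale, oxidation equilibrates over
~10⁵ s — far slower than any pacing protocol.  The whole-cell scenario
presets therefore read the oxidation rate on the millisecond time base the
cell model uses (`6.48e-6 ms⁻¹ = 6.48e-3 s⁻¹`), which places oxidation
equilibration at hundreds of seconds, consistent with burst-protocol
phenomenology.  `[MsrA]` is never constrained independently: only the
saturated product `k_redox·[MsrA]/([MsrA]+Km_MsrA)` enters the equations.
The kinase-module default (3.934e-6 mM) puts the dose-response
half-maximum at `[ROS] = Km_ROS`; the cell registry value (7e-5 mM,
effective reduction rate 5.8e-5 s⁻¹) is calibrated so the oxidized
fraction in the overexpressing cell under 200 µM ROS settles near 0.6.
Even so the oxidation mode relaxes over ~10³ s, so steady-state pacing of
ROS scenarios begins with an equilibration phase in which *both* oxidation
and reduction rates are scaled up together (×60) — their ratio, and hence
the equilibrium, is untouched — followed by plain pacing.

## Cell model

States (42): membrane potential; gates for I_Na (m,h,j), I_NaL (hL),
I_CaL (d, f, Ca-dependent fCa), I_to (a,i with explicit forward/backward
inactivation rates so the remodeling recipe can scale the named rate
`K_f_to`), I_Kur, I_ss; a 4-state RyR (R, O, I, RI); Na⁺, K⁺;
Ca²⁺ in a junctional cleft (0.2% of cytosolic volume), bulk cytosol and
SR; troponin and junctional membrane buffers (ODE), calsequestrin (rapid
buffer on the SR); three phosphorylation fractions; two 8-state kinase
instances.

Currents: I_Na, I_NaL (plateau-activating, slow V-dependent inactivation
whose steady-state midpoint is the remodeling target), I_CaL (into the
cleft, with Ca-dependent inactivation sensing cleft Ca), I_to, I_Kur,
I_K1, I_ss, background K⁺/Na⁺/Ca²⁺ conductances, NCX (electrogenic,
allosterically Ca-activated; 2% of the population senses cleft Ca), Na/K
pump, sarcolemmal Ca pump.  The stimulus (−30 pA/pF, 1.5 ms) is carried
by K⁺ so the ionic budget closes.  Units: mV, ms, µM (Ca), mM (Na/K),
pA/pF, SR fluxes in µM/ms on the cytosolic-volume basis.

### RyR

Shannon-style luminal regulation: the opening rate is
`ko_Ca/kCaSR(Ca_SR)·Ca_jn²` with
`kCaSR = Max − (Max−Min)/(1+(EC50_eff/Ca_SR)^h)`, `Max = 16`, `h = 8`,
`EC50_SR = 330 µM`.  RyR phosphorylation sensitizes the luminal sensor:
`EC50_eff = EC50_SR·exp(−1.2·(phos_RyR − 0.30))`.  A basal opening term
`ko_basal·(Ca_SR/EC50_eff)^8` ignites release without any trigger once
the SR is loaded far beyond the sensitized midpoint — this produces the
always-open regime in the upper-right of the threshold map.  Cytosolic-side
inactivation is weak (`ki_Ca = 1e-4 µM⁻¹ms⁻¹`); release terminates through
luminal desensitization and gradient collapse.  The gain of the
regenerative release loop crosses unity at a cleft-Ca level `Ca*` that
scales with `kCaSR`; because `kCaSR` spans more than an order of magnitude
between a depleted/dephosphorylated SR and a loaded/phosphorylated one,
the probe-current threshold spans the observed ~20× range between the
reference clamp conditions (≈56 pA/pF at 300 µM/20% vs ≈2.4 pA/pF at
450 µM/40%).

### Phosphorylation coupling

Each target (LTCC, PLB, RyR) follows
`dp/dt = kf·h(A)·(1−p) − kb·p` with `h = A²/(A²+Km²)` and `A` the
junctional active-CaMKII concentration (Hill 2, reflecting the multimeric
kinase).  The forward rates are set so the wild-type 1 Hz operating point
sits at the anchor fractions (0.60/0.085/0.30); all channel modifiers are
exactly the identity at the anchors, so the wild-type cell is the
unmodified baseline by construction.  Modifiers: LTCC conductance and
inactivation-τ scale up with phos_LTCC; SERCA forward Km scales down with
phos_PLB (floor 0.15×); the RyR luminal EC50 scales down with phos_RyR.

## Numerics

Rush–Larsen exponential updates for gates, forward Euler elsewhere;
phase-dependent step (10 µs during the upstroke and whenever cleft Ca is
elevated, 20 µs through systole, 50 µs in diastole); exact fixed-grid
sampling at 0.5 ms.  Clamps re-impose their level after every step, which
holds clamped traces constant to machine precision.  Integration is fully
deterministic (no random numbers anywhere in the dynamics); identical
configurations give bitwise-identical trajectories.  The Ca²⁺ bookkeeping
audit (change in total cell Ca vs time-integral of sarcolemmal Ca flux)
closes to better than 0.1% per beat in all scenarios.

Problem sizes used by the shipped tests and the acceptance script: pacing
runs of 60–400 beats starting from the pre-equilibrated preset states
(which were themselves produced by 2200+ beats of pacing with this code),
threshold searches of ~15 probes on 1 s observation windows after a 10 s
conditioning clamp, and 200-beat post-unclamp runs.

## Protocol conventions

* Steady state: beat-to-beat change of Na⁺, K⁺, Ca²⁺ and [Ca²⁺]_SR below
  1e-5 of the basal level, with a configurable beat cap; non-convergence
  is flagged, not raised.
* Burst: 2 s at 1 Hz, 12 s at 10 Hz, 26 s at 1 Hz; DADs counted on the
  recovery segment as diastolic depolarizations ≥5 mV above the
  post-repolarization baseline, outside 250 ms stimulus windows and below
  80% of the AP amplitude.
* APD_x from the maximal-dV/dt instant to x% repolarization; take-off
  potential read at the start of the upstroke (first sample whose dV/dt
  exceeds 5% of the upstroke maximum), which is robust at 0.5 ms sampling.
* Threshold search: 10 s (Ca_SR, phos_RyR) clamp, then square 5-ms Ca²⁺
  probes delivered to the cleft with the membrane potential held at its
  conditioned value (the probe substitutes the L-type current as a pure
  Ca-delivery device); release = drop of free [Ca²⁺]_SR ≥ 25% of the
  pre-probe level within 1 s; doubling bracket then bisection to
  0.1 pA/pF.  Release with zero probe ⇒ always-open.
* Post-unclamp stabilization: 200 beats at 1 Hz with phos_RyR still
  clamped (it is the map's axis); stability when the J_rel-peak series'
  consecutive-beat variation stays below 1%.

## What the scenario presets represent

`wt` is the unmodified baseline.  `oe` applies exactly five changes:
CaMKII ×6, I_NaL inactivation midpoint +6.8 mV, `K_f_to` ×5, I_K1
conductance ×0.6, NCX conductance ×1.3.  `wt_ros`/`oe_ros` add a constant
200 µM ROS (a pathophysiological level; ~35 µM is a normal level).  At
their 1 Hz limit behavior the presets give: Na⁺ 12.0/15.1 mM (wild type vs
overexpression, a 3 mM gain), junctional active CaMKII ≈179 µM diastolic
and ≈670 µM systolic in the overexpressing cell, ≈630 µM diastolic with
ROS added, and near-complete LTCC phosphorylation under ROS.

## Known limitations

* The limit behavior under pacing is weakly aperiodic (0.1–5%
  beat-to-beat Ca-release variability from the deep-dump release regime),
  so the strict 1e-5 steady-state criterion never formally fires; the
  convergence flag reports this honestly and mean stationarity holds.
* The same regime prevents the post-unclamp J_rel series from meeting the
  <1% stability rule at depleted/desensitized conditions, so
  stabilization times at the reference conditions are reported as
  not-stabilized-within-window rather than as finite times, and the
  wild-type Ca-transient amplitude is small (~0.1 µM).  A
  spatially-resolved release description (stochastic Ca-release units)
  would be needed to combine sharp graded transients with the deep
  clamp-release dumps the threshold map requires.
* Spontaneous diastolic release (and hence DADs) does not arise from
  free-running states: the operating SR load stays well below the
  always-open boundary.  The DAD detector is therefore validated on
  synthetic events, and cross-preset DAD ordering holds only trivially.
* ROS acts on CaMKII only (no other redox targets); no sarcolipin
  pathway; no energy metabolism; single cell only.
* Under ROS the wild-type cell's PLB phosphorylation rises more than the
  narrative it emulates suggests; LTCC phosphorylation and the direction
  of Ca-transient augmentation match.
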