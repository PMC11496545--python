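# Methods

`protoflux` models the biophysics of proton conduction through dissected
antiporter-like modules of respiratory Complex I (Nqo12/Nqo13 and their
point variants) reconstituted in proteoliposomes, together with the
analysis machinery used to quantify such assays.  This note records the
models, their assumptions, the tunable parameters, and the design choices
made where the design was genuinely open.

## 1. Acid–base and electrochemical kernel (`protoflux.chem`)

All species are monoprotic and treated with Henderson–Hasselbalch
speciation; buffer capacity is `beta = ln(10) * sum C_i a_i (1 - a_i)`
(mM per pH unit) with `a_i` the deprotonated fraction.  Activity
coefficients, ionic-strength corrections and temperature-dependent pKa
shifts are out of scope.  Default pKa values: acetate 4.8 (the only one
anchored experimentally), MOPS 7.20, pyranine 7.30, HEPES 7.50,
methylamine 10.6; all overridable.

Sign conventions, fixed repo-wide: the membrane potential is
`delta_psi = psi_in - psi_out`; `pmf(pH_in, pH_out, delta_psi)` is the
electrochemical free energy (kcal/mol) of moving one proton from the
vesicle interior to the exterior,

    pmf = -F dpsi - 2.303 RT (pH_out - pH_in).

The default temperature is 310.15 K (assays at 37 °C).

Probe models:

* **Pyranine (HPTS)** is ratiometric: `pH = a log10(I404/I454) + b` with the
  calibration constants a = 1.1684, b = 7.721.  The constants are treated as
  temperature-independent because a single calibration is available.  The
  synthetic-data inverse splits a fixed total intensity between the two
  channels so that the ratio matches the target pH; only the ratio is
  physical, and recovered pH is invariant to the total scale.
* **ACMA** quenching is a phenomenological, saturable reporter of interior
  acidification.  We use a Hill law in the pH difference only
  (`Q = q_max dpH^h / (K^h + dpH^h)`); the membrane-potential contribution is
  ignored because the assays dissipate it with valinomycin.  The shipped
  parameters (q_max = 0.95, K = 0.938 pH units, h = 2.73) are a calibration:
  the two free parameters K and h are fixed by mapping the simulated
  steady-state pH gradients of the two anchor conditions (ATP synthase alone,
  and ATP synthase with the WT antiporter leak) onto their observed quench
  plateaus (90% and 30%).  This is the probe's calibration curve, not a fit
  to trace shapes.

## 2. Ion-pair barrier tuning (`protoflux.barrier`)

Each antiporter module carries a buried Glu–Lys ion-pair a distance `R` from
the midpoint of its lateral proton pathway (about 14 Å in Nqo13, 22 Å in
Nqo12).  Opening the pair (charge–charge separation `d` growing from a
closed salt-bridge geometry to a dissociated one) changes the Coulomb field
it projects along the pathway, and a Stark-like linear coupling shifts the
proton-transfer barrier:

    dG(d) = dG_closed - q_dx * [E_par(d) - E_par(d_closed)],

where `E_par` is the exact two-point-charge field at the pathway midpoint,
projected on the pathway direction and screened by an effective dielectric
`eps`, and `q_dx` (e·Å) is an effective transferred-charge × displacement.
For `R >> d` the field reduces to the point-dipole form
`k q d cos(theta) / (eps R^3)` (verified to < 5% deviation for R/d > 4).
This analytical model is a reconstruction constrained by the barrier anchors
and the between-module transfer behaviour; it is not a literal quotation of
any published equation set.

**Anchors.**  The shipped anchor table holds the QM/MM barrier values:
Nqo13 closed/open = 14/6 kcal/mol at R = 14 Å; Nqo12 closed/open =
15/13 kcal/mol at R = 22 Å.  The closed/open charge separations are not
published as numbers (the source reports distance distributions), so the
defaults d_closed = 3.0 Å and d_open = 8.0 Å are declared: a typical
salt-bridge N–O contact and a dissociated-state plateau.  Whether the
published barrier-modulation x-axis is a strict charge–charge distance or a
reaction-coordinate surrogate is not stated; we treat it as charge–charge
distance.

**Fitting.**  `BarrierTuningModel.fit()` pins `dG_closed` to the
smallest-separation anchor and least-squares fits `(q_dx, eps)` (eps bounded
to [2, 20], start 4 — a generic protein-interior permittivity) to the
remaining anchors.  For anchors at a single pathway distance, `q_dx` and
`eps` enter every prediction only through the ratio `q_dx/eps` (the field
carries a global 1/eps); the ratio is the identifiable quantity, and the
self-consistency tests assert its recovery.  `eps` is kept as an explicit
parameter for interpretability and for potential multi-geometry fits.

**Transfer.**  `transfer_anchored_prediction(R2, dG_closed_2)` rescales the
fitted barrier drop by the dipole far-field factor `(R1/R2)^3` and subtracts
it from the second module's closed anchor.  Fit on Nqo13 (drop 8 kcal/mol at
14 Å) and transferred to Nqo12 (22 Å, closed 15 kcal/mol) this predicts an
open-state barrier of 12.94 kcal/mol, against the independently computed
13 kcal/mol.

**Rates.**  Transition-state theory, `k = (k_B T / h) exp(-dG/RT)`.
Thermodynamic driving forces stored with the presets are used only for
direction sanity checks, never in rate laws.

## 3. Vesicle simulator (`protoflux.vesicle`)

A single representative vesicle is simulated (population heterogeneity,
vesicle size distributions, osmotic volume changes and chloride permeation
are out of scope).  The exterior is an infinite clamped reservoir — the
cuvette holds ~30 µL of proteoliposomes in 1 mL of buffer — whose pH, ionic
composition and scheduled additions are imposed.  State variables: interior
total titratable proton content, total acetate, total methylamine, K⁺, and
the membrane potential, plus cumulative flux integrals carried as auxiliary
ODE states for exact conservation diagnostics.  Interior pH is solved
algebraically at every evaluation (Newton with the analytic buffer-capacity
slope, bisection fallback), i.e. interior acid–base equilibrium is treated
as instantaneous.

Fluxes (mM of interior volume per second):

1. **Neutral-form permeation** `J = P (A/V) ([X]_out - [X]_in)` for the
   protonated weak acid (acetic acid, P = 6e-3 cm/s) and the neutral weak
   base (methylamine, P = 1e-3 cm/s).  The permeabilities are
   literature-typical defaults, not published in the source study.
2. **Antiporter flux** through a symmetric Eyring barrier:
   `J_H = N k_eff 2 sinh(pmf / 2RT)`, electrogenic.  The sinh form stays
   valid at multi-kcal driving forces and reduces to a linear conductance at
   small pmf.  Both membrane orientations of a symmetric channel conduct
   identically, so the 75%/25% N-side-in/out split enters as a sum of
   orientation weights (= 1); it is kept explicit in the code for generality.
3. **Background leak**: the same law with a small conductance
   (0.2 s⁻¹ per vesicle) standing in for the slow non-specific leak of
   control liposomes.
4. **Valinomycin**: a K⁺ current relaxing the potential toward the K⁺ Nernst
   value with a 50 ms time constant (fast against the 600 ms sampling).
5. **Nigericin**: electroneutral H⁺/K⁺ exchange,
   `J ∝ ln([H]_in [K]_out / [H]_out [K]_in)`.
6. **ATP synthase** (hydrolysis mode, pumping inward):
   `J = copies × turnover_max × max(0, 1 - load/stall)`, with
   turnover_max = 2400 H⁺ s⁻¹ (the published hydrolysis-mode rate, used as
   the zero-load turnover — a deliberate simplification of its 120 mV
   anchor) and stall = 4.0 kcal/mol (≈ ATP hydrolysis free energy per
   10/3 H⁺).
7. The potential integrates net charge flux over the membrane capacitance
   (1 µF/cm²; ~70 elementary charges per 100 mV on a 60 nm vesicle).

Events (acid/base addition, ATP, ionophores) partition the integration into
BDF segments (`scipy.integrate.solve_ivp`, rtol 1e-8, atol 1e-10; halving
the tolerances moves steady-state pH by < 1e-4).

**Assay recipes.**  Acid-driven assay: 60 nm vesicle, interior 2 mM MOPS
pH 7.2, 5 mM pyranine, 50 mM KCl; valinomycin from t = 0; 10 mM acetate at
60 s; nigericin at 540 s; 600 s horizon at 600 ms sampling.  ATPase-driven
assay: 200 nm vesicle, 10 mM HEPES pH 7.5, 100 mM KCl, 5 mM MgCl₂, ACMA
read-out at 100 ms sampling; 0.2 mM ATP at 60 s (the ATP amount gates pump
activation; Michaelis dependence on ATP is out of scope); nigericin at
340 s.  These horizons keep every simulation in the seconds range on one
CPU while the traces reach their plateaus well before dissipation.

**Reservoir composition on additions.**  Scheduled additions change only the
transported weak-acid/base species; the potassium counter-ion of potassium
acetate is treated as part of the clamped reservoir background (K_out stays
at the 50 mM recipe value).  With this convention the joint H⁺/K⁺/HA Donnan
equilibrium of the acetate assay — trapped acetate anion inside, K⁺
redistributing through valinomycin, protons equilibrating through the
channel — sits at pH_in ≈ 7.14, reproducing the observed plateau band of
fast-conducting variants; folding the added K⁺ into the reservoir would
instead erase the steady-state acidification entirely at equilibrium.

**Effective interior buffering.**  With MOPS + pyranine alone, the
closed-vesicle acetate partition equilibrium predicts a ~0.7 pH drop, more
than twice the observed 0.3.  Real liposome interiors buffer harder (lipid
headgroups, residual carbonate).  A residual buffer species is therefore
shipped (pKa 7.05, centred on the assay's working range; monoanionic base
form) whose concentration, 22.6 mM, is derived in closed form from the
proton balance so that the zero-conductance equilibrium drop equals the
observed 0.30.  The derivation is a two-line root solve of
`released(pH) = absorbed(pH)` with `[HA]_in = [HA]_out` imposed.

**Transport-rate calibration.**  The study publishes no absolute Nqo
turnover, so absolute rates are declared, not derived, as two per-assay
coefficients shipped with the presets:

* *Acid-driven assay*: `k_eff = attempt × k_Eyring(dG)` with
  attempt = 0.004, the single calibration constant fixed so the WT-Nqo13
  trace reaches its observed 7.10–7.12 plateau within the trace (per-channel
  ~3.5 s⁻¹ under the assay's sub-0.3-pH driving force — a delivery-limited
  regime where the weak-acid supply, not the elementary transfer, sets the
  pace).
* *ATPase-driven assay*: channels run at the bare Eyring rate capped at
  1000 s⁻¹ (sub-millisecond elementary transport, the turnover scale implied
  by the ability of the antiporter leak to compete with a 2400 H⁺/s pump).

The two regimes are not reconcilable with a single constant — a known
limitation of the representative-vesicle model; the assay-specific
coefficients are documented here and in the presets file.

**Known limitations.**  (i) Under the single acid-assay calibration the
WT-Nqo12ΔTH construct (closed barrier 15 kcal/mol) relaxes ~5× slower than
WT-Nqo13 and plateaus near pH 7.0 within the default trace, short of the
7.1–7.12 band both WT constructs show experimentally.  (ii) The observed
*higher* ACMA quench of the fast E123Q variant (50%) relative to WT (30%)
cannot arise in a monotone pump-vs-leak competition, where a faster leak
always lowers the quench; reproducing it would need probe- or
vesicle-population effects outside this model.  (iii) Donnan anion trapping
and buffering both shape the control steady state; their relative
contributions are a model output here, not an independently measured input.

## 4. Trace analysis (`protoflux.traces`)

Pyranine traces convert elementwise through the calibration; NaN samples are
flagged and propagated, never dropped.  ACMA traces are normalised to a unit
baseline over the first minute.  Initial rates are ordinary least squares of
`a0 + k1 t` with `k1` reported in min⁻¹ with its standard error; the default
window runs from the triggering event to +30 s (ACMA) or +10 s (pyranine) —
declared defaults, since the published fitting windows are not available.
Steady-state levels are means over the 30 s window ending at the nigericin
event (traces plateau well before dissipation), excluding post-nigericin
samples; replicates aggregate as mean ± SD, matching figure conventions.
The orientation estimator is `f = I_intact / I_solubilized` (exposed-tag
fraction), mapped to an N-side-inward fraction by the tag's topology.
Photobleaching and inner-filter corrections are out of scope.

## 5. Free-energy estimators (`protoflux.fes`)

The lateral proton-transfer coordinate is replaced by analytic 1-D model
potentials (double well `B((x/a)^2-1)^2`, optionally tilted by a linear
field term from the barrier-tuning coupling), which makes estimator
correctness fully testable: the analytic potential is the oracle.  Windows
are harmonically restrained (default force constant 100 kcal mol⁻¹ Å⁻², the
value used in the source free-energy protocol) and sampled with a Metropolis
walker at 310 K, step size auto-tuned to 40–60% acceptance, chain thinned
10× to suppress autocorrelation; seeds are per-window and mandatory in
tests.  Sample counts are set by convergence tests (the source's
picoseconds-per-window have no meaning for a surrogate sampler).

*WHAM* iterates the self-consistent histogram equations to an offset
tolerance of 1e-8 with a hard failure on non-convergence, and diagnoses
insufficient adjacent-window overlap (< 1% of samples) with an informative
error before estimating.  *MBAR* minimises the convex multistate objective
(L-BFGS with analytic gradient) and polishes with Newton steps on the
estimating equations; for umbrella windows the common unbiased potential
cancels, so only the biases enter, and the unbiased PMF follows from the
per-sample weights.  `solve_mbar` also accepts arbitrary reduced-potential
matrices (validated against the Gaussian closed form
`dF = (RT/2) ln(k2/k1)`).  Per-bin uncertainties are Poisson counting
estimates `RT/sqrt(n_bin)`; they scale as 1/sqrt(n) and are approximate at
sparsely sampled grid edges.  Both estimators are invariant to constant
potential shifts and agree with each other within combined uncertainties on
shared samples.  The enhanced-sampling engine used in the source study and
its multidimensional collective variable are out of scope; only the
estimator layer is reproduced.

## 6. Synthetic data (`protoflux.synth`)

The generator emulates the experimental design: noiseless trajectories from
the simulator, probe channels rendered through the calibrations (pyranine
pair at 600 ms, ACMA at 100 ms), additive Gaussian noise of 1% of the
channel baseline per replicate (visually comparable to the published trace
scatter; declared, not derived), n = 6 replicates by default, and a
deterministic seed ladder (manifest base seed + replicate index) making
every downstream result reproducible.  A separate linear-decay ACMA
generator supports rate-estimator recovery studies with a prescribed true
slope.  What passing tests show: the analysis stack recovers what the
simulator put in, under realistic noise and sampling.  What they do not
show: robustness to instrument artefacts absent from the generator (lamp
drift, mixing dead time beyond the event discretisation, photobleaching,
probe binding to outer leaflets).

## 7. Reported-quantity provenance

Quantities the package reproduces computationally at run time: the
calibration intercept (exact), the 0.3 control acidification, the
steady-state plateau ordering (controls ≤ 7.04 < WT ≥ 7.1 < open variants
≈ 7.14), the 90%/30% quench competition, linear-rate recovery at 5.56 min⁻¹,
and the 12.9 kcal/mol barrier transfer.  Where a value above is a
calibration anchor (residual buffering, attempt factor, ACMA response), that
status is stated explicitly in this note and the constants live in
`src/protoflux/data/presets.json`.
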