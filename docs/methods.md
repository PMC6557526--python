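# Methods

This document describes the models implemented in `dmt1flux`, the
conventions and defaults they use, the numerical choices behind the
simulation and fitting machinery, and the known limitations.

## 1. Biological setting and assumptions

Polarized Caco-2 monolayers on permeable inserts are exposed to
sequential apical iron challenges (fresh medium with 20 μM Fe²⁺–
ascorbate for 15 min, replaced after an ice-cold wash). Measured uptake
is the cumulative iron in cells plus basolateral medium (pmol/insert).
A second challenge is absorbed substantially less than the first — the
*mucosal block* — and the hypothesis encoded here is that the block is
caused by endocytic relocation of the apical transporter DMT1.

Modeling assumptions:

* Only DMT1-mediated apical transport is modeled; no apical reductase,
  basolateral exporter or systemic regulation dynamics.
* The transporter population is represented by occupancy fractions of
  mechanistic states, `P1..P6`, with `ΣP = 1`:
  `P1` empty membrane transporter facing the lumen, `P2` iron-bound,
  `P3` internally oriented (translocating), `P4` empty after release,
  `P5` (and `P6` in the swing model) endocyted states.
* Iron in vesicles of the endocyted transporter can be released to the
  intracellular pool; the vesicle volume enters through a geometric
  factor γ (below).
* The ice-cold wash between challenges halts all processes, so the wash
  is instantaneous: `P` and `FeIN` carry over, `FeOUT` is reset to the
  fresh challenge concentration.
* All times in minutes, concentrations in μM, volumes in μL, lengths in
  μm (1 μm³ = 10⁻⁹ μL).

## 2. Geometry

The cell is a cylinder of height `h_c = 29.6` μm and diameter
`d_c = 6.2` μm, giving a surface area

    A_E = 2π (d_c/2) h_c + 2π (d_c/2)² = 636.93 μm².

With a vesicle volume per membrane area `R_V = 0.04` μm³/μm² and a
release-competent fraction `release_fraction = 0.01` (the lower bound of
the plausible 1–5% range; only this value matches the derived vesicle
volume below), the iron-releasing vesicle volume is

    V_V = release_fraction · R_V · A_E · 10⁻⁹ ≈ 2.5×10⁻¹⁰ μL,

and the volume correction factor scaling vesicular iron release is

    γ = V_V / V_cb ≈ 2.5×10⁻¹³,

where `V_cb = 1000` μL is the pooled cellular + basolateral volume and
`V_a = 200` μL the apical medium volume. The monolayer volume `V_m`
appears in no rate equation and is carried for completeness only.

## 3. Switch model

States `P1..P5`. Endocytosis (`k45`, second order in `FeOUT`) and
exocytosis (`k54`) are mutually exclusive: in *endocytic* mode `k54` is
zeroed, in *exocytic* mode `k45` is zeroed.

    dP1/dt = −k12·P1·FeOUT − k14·P1 + k41·P4
    dP2/dt =  k12·P1·FeOUT − k23·P2
    dP3/dt =  k23·P2 − k34·P3
    dP4/dt =  k34·P3 + k14·P1 − k41·P4 + k54·P5 − k45·FeOUT·P4
    dP5/dt =  k45·FeOUT·P4 − k54·P5
    dFeIN/dt  = k34·DMT1_E·P3 + γ·k54·DMT1_E·P5
    dFeOUT/dt = −(V_cb/V_a)·dFeIN/dt

Mode switching is hysteretic: endocytic → exocytic when the endocyted
fraction reaches `P5 ≥ alpha_E` (default 0.9890), exocytic → endocytic
when the membrane fraction reaches `P1+P2+P3+P4 ≥ alpha_M` (default
0.9780). Comparisons are closed (≥): a tie resolves toward switching.
The model starts in endocytic mode with `P1 = 1`, and (by default,
configurable) re-enters endocytic mode at each new challenge.

Thresholds are validated as strictly positive but *may exceed 1*: an
unreachable threshold simply pins the model in its current mode. This is
deliberate — the sensitivity analysis perturbs `alpha_E` by +10% to
1.0879, which must be admissible.

## 4. Swing model

States `P1..P6`. Endocytosis and exocytosis run simultaneously through
three competitive autocatalytic reactions (a minimal chemical-oscillator
motif) on `P4`, `P5`, `P6`:

    endo = ρ·k45·FeOUT·P4·P5     (membrane → endocyted, autocatalytic in P5)
    conv = k56·P5·P6             (P5 → P6 conversion)
    exo  = ρ·k64·P6·P4           (endocyted → membrane, autocatalytic in P4)

    dP1/dt = −k12·P1·FeOUT − k14·P1 + k41·P4
    dP2/dt =  k12·P1·FeOUT − k23·P2
    dP3/dt =  k23·P2 − k34·P3
    dP4/dt =  k34·P3 + k14·P1 − k41·P4 + exo − endo
    dP5/dt =  endo − conv
    dP6/dt =  conv − exo
    dFeIN/dt  = k34·DMT1_E·P3 + γ·k64·DMT1_E·P6
    dFeOUT/dt = −(V_cb/V_a)·dFeIN/dt

The oscillator needs seeding: initial conditions are `P1 = 0.98`,
`P5 = P6 = 0.01` (it stalls if either internal state starts at zero).

### Kinetic correction factor ρ

Repeated challenges damp DMT1 cycling. With `j` the 1-based index of the
current challenge, `FeUP(j)` the intracellular iron recorded when
challenge `j` was applied, and `FeCHG(j)` its apical concentration:

    ρ(t, j) = 1 − 2.8 · (FeIN(t) − 1.67·FeUP(j)) / FeIN(t) · FeCHG(j−1)/FeCHG(j)

The 1.67 factor encodes the literature estimate of the block magnitude
(total uptake after two equal doses ≈ 1.67× a single dose); 2.8 sets the
damping gain. Conventions:

* `FeCHG(0) = 0`, so ρ ≡ 1 throughout the first challenge.
* ρ is evaluated from the instantaneous `FeIN` inside the RHS
  (time-continuous), not frozen per step.
* At the start of a second equal-concentration challenge `FeIN = FeUP`,
  giving ρ = 1 − 2.8·(1 − 1.67) = 2.876 exactly; ρ then decays as iron
  accumulates and can go negative late in a challenge. ρ is *not*
  clamped by default (the equations are implemented literally); an
  optional `clamp_rho` flag floors it at 0.
* `FeIN ≤ 0` while evaluating ρ for `j ≥ 2` cannot occur after a
  completed first challenge and is treated as an error.

### Effectiveness ratio

`DMT1_E = DMT1 / Φ` is the effective transporter amount — total DMT1
divided by the transport-cycle effectiveness Φ of the model. Neither
DMT1 nor Φ is identifiable individually; the ratio between models,
`Φ_switch/Φ_swing = DMT1_E(swing)/DMT1_E(switch) = 46156.25/566.10 ≈ 81.5`,
expresses how much more effective the switching mechanism would have to
be to explain the same uptake.

## 5. Default parameters

Shipped defaults (also packaged as YAML under `dmt1flux/data/`) are the
published jackknife estimates. Units: `k12`, `k45`(switch/swing) are
min⁻¹·μM⁻¹; other k's min⁻¹; `DMT1_E` μM; thresholds dimensionless.

Switch: k12 = 5.31×10⁻⁶, k23 = 0.9104, k34 = 2.2193, k41 = 0.3731,
k14 = 11.2703, k45 = 0.0630, k54 = 0.6492, DMT1_E = 566.10,
alpha_E = 0.9890, alpha_M = 0.9780.

Swing: k12 = 1.68×10⁻⁷, k23 = 1.6608, k34 = 1.3221, k41 = 0.7064,
k14 = 30.7036, k45 = 0.2887, k56 = 3.2082, k64 = 2.9639,
DMT1_E = 46156.25.

## 6. Numerical integration

* Stiff-capable adaptive solver (LSODA) with `rtol = 10⁻⁸`,
  `atol = 10⁻¹⁰` defaults; the `k14 ≈ 30` min⁻¹ relaxation against a
  15-min horizon is mildly stiff.
* Switch-mode transitions are located by root-finding on the threshold
  functions (scipy terminal events, rising direction), and integration
  restarts with the flipped mode. Detecting crossings on output samples
  would chatter at coarse grids.
* The uptake observable is `(FeIN(t) − FeIN(t_start))·V_cb` in
  pmol/insert, baseline-subtracted per challenge (matching the isotope
  accounting); a cumulative-from-origin baseline is also exposed.
* An optional `max_rhs_evals` budget aborts an integration (as a
  `RuntimeError`) after a fixed number of right-hand-side evaluations.
  Some admissible but pathological parameter sets drive the adaptive
  solver through millions of tiny steps; during fitting these candidates
  are abandoned and penalized instead of stalling the optimizer.

Verification: trajectories were cross-checked during development against
an independent `deSolve`(R)/lsoda integration (agreement to ~10
significant digits in `FeIN`), and the test suite asserts
centered-finite-difference agreement with the RHS (< 10⁻³ relative, away
from switching events), transporter and iron conservation, and
grid-refinement stability.

## 7. Parameter estimation

Only first-challenge data are used for fitting; second-challenge data
are validation-only (the block magnitude is already fixed inside ρ and
is not re-estimated).

* **Objective**: mean squared error (pmol²) between model uptake and
  observations; observations default to per-time-point means (5 per
  challenge), with replicate-level (15 points) as a documented option.
* **Optimizer**: Nelder–Mead in log-parameter space (positivity and
  scale equalization across ~11 orders of magnitude); at most 5000
  iterations, convergence at 10⁻⁸ tolerances. The objective returns a
  large penalty (10¹²) for failed integrations, non-finite errors, and
  candidates beyond 15 nat-log units of the start, so the simplex backs
  away from pathological regions. Optional deterministic restarts
  (`n_restarts`, seeded Gaussian jitter of the start in log space) guard
  against local minima; everything is bit-reproducible for fixed
  arguments.
* **Jackknife**: each training observation is left out once, parameters
  are refit, and the dropped point is predicted. `MSE_jk` is the mean of
  squared leave-one-out errors (a raw-sum option exists). Point
  estimates are fold means; the jackknife standard error
  `SE = sqrt((n−1)/n · Σ(θ_i − θ̄)²)` yields confidence half-widths via
  a t-quantile (df = n−1) and two-sided p-values against H₀: θ = 0 (the
  conventional choice; the null is not otherwise specified).
* **Model ranking**: `AICc = n·ln(MSE) + 2K + 2K(K+1)/(n−K−1)`. With
  n = 5 mean observations and K = 9–10 parameters the correction is
  undefined (n ≤ K+1) and the implementation refuses to extrapolate;
  AICc is therefore evaluated at the replicate level (n = 15) by
  default, and comparisons require both fits to share the same
  convention. Identifiability is *not* claimed: 9–10 parameters against
  5 observations is under-determined by design of the experiment; only
  the predicted curve is validated.

## 8. Sensitivity analysis

One-at-a-time ±10% perturbations of each parameter around its nominal
value; the output functional is `FeIN` at a fixed evaluation time
(default 15 min = end of the first challenge — the analysis never states
the evaluation time, so it is exposed as a parameter). The normalized
coefficient

    r± = [(FeIN_perturbed − FeIN_nominal)/FeIN_nominal] / (±0.10)

is computed as a forward difference against the nominal run, separately
for the increase (r⁺) and decrease (r⁻); `r*` is the larger-magnitude of
the two and classifies influence: negligible |r*| ≤ 0.25 < low ≤ 0.5 <
regular ≤ 1 < high (inclusive upper bounds).

## 9. Synthetic data

`generate_uptake_dataset` simulates a model through the protocol and
samples noisy replicate uptake values at the sampling times. Defaults
mirror the experimental design: two 15-min challenges at 20 μM, sampling
at 3, 6, 9, 12, 15 min, triplicates. The default noise is multiplicative
Gaussian with cv = 0.20, *a stand-in choice* matched visually to the
replicate scatter of the reported experiments (no noise law is
published); additive Gaussian noise is available, draws are clamped at
zero, and all randomness flows from one explicit seed. Cumulative-uptake
monotonicity is not enforced on noisy replicates, only on noise-free
means. Dataset I/O uses a flat CSV schema
(`challenge,time_min,replicate,uptake_pmol`) with validation that names
offending rows; a simple XLSX reader maps spreadsheet fixtures into the
same schema.

## 10. Limitations and known discrepancies

* **Influence-class tables are not fully reproducible.** The golden
  sensitivity coefficients (swing k12 r⁺ ≈ 0.9999, switch DMT1_E r⁺ ≈
  1.0030) reproduce within tolerance under the defaults. The *full*
  published class tables do not, and the acceptance test asserting them
  is deliberately left failing rather than weakened:
  * The published k23 and k34 rows (r ≈ 0.98, "Regular") are
    unreachable at *any* evaluation time: P2 and P3 equilibrate within
    ~1 min (quasi-steady state), after which cumulative `FeIN` is
    controlled by the `k12·P1·FeOUT` influx; computed coefficients are
    ~0.001–0.15. This was confirmed with an independent integrator, so
    it reflects the published tables, not an implementation error.
  * The remaining rows are evaluation-time sensitive: the swing-model
    oscillator rows (k45, k56, k64) match the published classes at an
    evaluation time of ~9 min but not at 15, while several switch-model
    rows match at 15 but not 9. No single evaluation time reproduces
    both tables.
* **Printed AICc values are not reproducible as stated** (the
  small-sample correction is undefined at n = 5, K = 9–10; whatever n
  and formula produced the printed values cannot be recovered). Only the
  *ordering* (swing preferred) is asserted, on shared data at the
  replicate-level convention.
* **The reported 2000 pmol initial dose conflicts with the protocol
  volumes** (`V_a·FeCHG` = 200 μL × 20 μM = 4000 pmol). The published
  uptake-fraction arithmetic (9.4/2000 = 0.47%, 3.8/2000 = 0.19%) is
  preserved as printed and flagged, not resolved.
* ρ is not clamped by default and can make effective trafficking rates
  negative late in a repeated challenge; within the standard 15-min
  windows this does not occur.
* The `FeUP` indexing convention ("amount of intracellular iron at the
  moment the current challenge is applied") is one reading of an
  ambiguous definition; it is the one that yields ρ = 2.876 at the start
  of a second equal challenge.
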