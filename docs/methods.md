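# Methods

This note documents the models, numerical choices and known limitations of
`scn1a_dynamics`. It is written for a reader who wants to know exactly what
the package computes and what its tests do and do not establish.

## 1. The scientific setting

NaV1.1 (encoded by *SCN1A*) is the brain sodium channel whose loss- and
gain-of-function variants underlie Dravet-spectrum epilepsies, many of them
temperature sensitive. The package implements a two-stage analysis of one
such variant (A1273V) characterised at 37 °C and 40 °C:

1. **Channel stage** — whole-cell voltage-clamp characterisation of channel
   gating: conductance–voltage (G–V) curves, steady-state fast inactivation
   (SSFI), open-state inactivation decay, recovery from inactivation, and a
   two-factor statistical test for genotype differences in temperature
   sensitivity.
2. **Neuron stage** — a regular-spiking cortical Hodgkin–Huxley (HH) model
   whose sodium gating steady states are replaced by Boltzmann curves
   carrying the measured condition parameters, simulated across stimulus
   currents and analysed for depolarisation block (oscillation-offset
   bifurcations, hysteresis).

Because raw patient-derived recordings are not distributed, the channel
stage operates on synthetic voltage-clamp sweeps with known ground truth
(section 3); the neuron stage operates on the published condition parameter
table (section 4).

## 2. Gating models

All sigmoid gating curves use one Boltzmann convention

    x_inf(V) = 1 / (1 + exp(-(V - V_half) / s)),

with s > 0 an increasing curve (activation) and s < 0 a decreasing one
(availability). Midpoints and slopes are in mV.

## 3. Synthetic voltage-clamp generator

### Model

Currents follow `I(t) = g_max · m(t)³ · h(t) · s(t) · (V − E_rev)` with
three independent first-order gates. Within each constant-voltage segment a
gate relaxes in closed form, `x(t) = x_inf + (x0 − x_inf)·exp(−t/τ(V))`, so
endpoints are exact (semigroup property holds to rounding; no ODE error) and
independent of the sampling interval. Time constants are bell-shaped,
`τ(V) = τ_base / cosh((V − V_half)/(2s)) + τ_floor`, peaking at each gate's
midpoint.

Two conventions matter for interpretation:

* the **activation gate relaxes toward the cube root** of the ground-truth
  conductance Boltzmann, so the steady-state conductance `m³` — the
  quantity a G–V analysis actually measures — carries the stated midpoint
  and slope. This makes "fitted G–V midpoint ≈ ground-truth midpoint" a
  meaningful recovery check rather than a quantity offset by `s·ln(2^(1/3)
  /(1−2^(1/3)))`-style cube corrections.
* the **slow-inactivation gate** `s` (available fraction
  `1 − a_slow · sigmoid(V)`, default a_slow = 0.35, midpoint −30 mV) engages
  only where fast availability is already near zero, so it leaves G–V and
  SSFI curves essentially untouched; its sole observable effect is making
  recovery from a 200 ms conditioning pulse double-exponential, which is
  what the recovery analysis fits. Defaults put the fast recovery constant
  at τ_h(−90) ≈ 7.0 ms and the slow one at τ_s(−90) ≈ 62 ms with a
  ~0.66/0.34 amplitude split.

### Protocols (defaults)

* activation: holding −90 mV, 20 ms steps −100…+60 mV in 10 mV increments;
* SSFI: 200 ms prepulses −130…+10 mV, 20 ms test pulse to 0 mV;
* recovery: 200 ms conditioning at 0 mV, recovery at −90 mV over 12
  log-spaced intervals 0.5–512 ms, 20 ms test pulse to 0 mV.

Sampling is 0.05 ms (20 kHz). Noise is i.i.d. Gaussian on current; the
pipeline default is 1 % of the peak current magnitude. Ground truth
defaults (G–V midpoint −20 mV / slope 7; SSFI −60 / −6; E_rev +45 mV;
g_max 0.05 µS) give ~1 nA peak inward currents, typical of good whole-cell
recordings; E_rev sits inside the protocol range so the reversal is
estimated from the peak I–V zero crossing rather than assumed.

### What the generator does *not* emulate

Series-resistance and space-clamp error, capacitive transients (traces
stand for P/4-subtracted records), seal drift, cell-to-cell variability,
and any temperature dependence inside the generator (conditions are
emulated by different ground-truth sets). Passing recovery tests therefore
show the *analysis* is unbiased for clean single-cell-like data, not that
it is robust to all recording pathologies.

## 4. Channel analysis stage

* **Peaks**: sample of maximal magnitude after a 0.2 ms blank window. The
  sweep-level fit wrappers first apply a 0.25 ms boxcar (the acquisition
  chain is low-passed at 5 kHz anyway); this suppresses the upward bias of
  sample-wise peak picking on noisy traces, which otherwise dominates the
  G–V midpoint error near the reversal potential.
* **Conductance**: `G = I_peak/(V − V_rev)` with V_rev the interpolated
  zero crossing of the peak I–V relation; points within 2 mV of V_rev are
  dropped. The Boltzmann fit for G–V uses a free amplitude (plateau level),
  standard practice that keeps noise-inflated saturation points from
  biasing the midpoint; reported curves are normalised to max 1.
* **SSFI**: test-pulse peaks normalised to their maximum, fit by a falling
  Boltzmann (unit amplitude).
* **Decay**: single exponential `A·exp(−t/τ) + C` from the peak to the end
  of the step.
* **Recovery**: `offset + A_f(1−e^(−t/τ_f)) + A_s(1−e^(−t/τ_s))`,
  trust-region least squares from three starts, τ sorted. When the two
  components are inseparable (amplitude fraction < 0.5 % or τ ratio < 2)
  the best single-exponential fit is returned with a fallback flag instead
  of pretending two components were resolved.
* **Temperature-sensitivity statistics**: ordinary least squares of
  `value ~ genotype + temperature + genotype:temperature` with genotype
  nominal and temperature continuous; the interaction is tested by the
  nested-model F statistic at α = 0.05. If not significant, the additive
  model is refit and main effects are reported from it (the two-step
  procedure). Per-voltage tests are left uncorrected by design, with a
  Holm-adjusted column available (`holm_adjust`) for transparency.

## 5. The neuron model

Membrane equation (mV, ms, µA/cm², mS/cm², µF/cm²):

    C dV/dt = I_stim − g_L(V−E_L) − g_Na·m³h·(V−E_Na) − g_K·n⁴·(V−E_K)
    dx/dt   = (x_inf(V) − x)/τ_x(V),   x ∈ {m, h, n}

Fixed parameters across conditions: C = 1 µF/cm² (stored as the published
0.010 µF/mm², an exact unit conversion), g_L = 0.0205, g_K = 5,
g_Na = 56 mS/cm², E_L = −70.3, E_K = −90, E_Na = +50 mV.

* `m_inf`, `h_inf` are Boltzmann curves with the condition-specific
  (V_2m, s_m, V_2h, s_h).
* `n` and **all time constants** come from Traub-type rate functions with
  threshold offset V_t (τ_x = 1/(α_x+β_x)); removable singularities are
  evaluated by their series limits.
* The fast-inactivation time constant is evaluated with the condition's
  `T_off` added to the voltage inside the h rate functions:
  `τ_h(V) = 1/(α_h(V+T_off) + β_h(V+T_off))`. Because the published T_off
  values are numerically ≈ −ΔV_2h, this is equivalent to shifting the h
  rate curves along the voltage axis by each condition's SSFI midpoint
  shift — the stated intent of the published normalisation — and it is the
  only composition (of four examined) that reproduces the published
  bifurcation phenomenology (section 7).

### V_t calibration

The five-step normalisation equates the WT-37 °C condition with the
baseline cortical parameterisation: Boltzmann fits to the baseline
steady-state curves `x_inf = α/(α+β)` on −120…0 mV (1 mV grid, unweighted)
must return the WT37 row. This pins V_t: at the committed value
**V_t = −65.0 mV** the fits give V_2m = −39.03, s_m = 7.41, V_2h = −43.32,
s_h = −4.04 (targets −39.0/7.4/−43.3/−4.0). Published parameter listings
variously give V_t = −55 or −60 mV; neither reproduces the published
WT37 midpoints under Traub-type rates (they give V_2m = −29 and −34
respectively), so V_t is treated as the calibration constant it effectively
is. `calibrate_vt()` re-derives it at runtime.

### Condition construction

Midpoints shift additively and slopes scale multiplicatively relative to
WT37; T_off is copied. Deltas are back-computed from the published rows, so
`apply_deltas(baseline, table1_deltas()[label])` reproduces each row
bit-exactly (verified: IEEE round-trip `b+(t−b)==t` and `s·(t/s)==t` holds
for every table value).

One printed value is sign-corrected: the AV40 inactivation slope appears as
+3.8 while the other three conditions are negative; +3.8 would make
availability *increase* with depolarisation (and abolishes all AV40 firing
in the model). It is stored as −3.8.

### Integration

Two integrators: LSODA (rtol 1e-8, atol 1e-10, max step 0.5 ms) for single
runs, and a fixed-step RK4 core (dt 0.02 ms default; numba-compiled when
available, identical arithmetic without it) for sweeps and f–I curves,
chosen for bitwise reproducibility. Gates are clamped to [0, 1] after each
RK4 step (first-order relaxation cannot leave the interval; clamping only
trims rounding spill). Halving dt leaves spike counts on the eight standard
runs (4 conditions × {0.2, 45}) unchanged and moves offset-current
estimates by less than one grid step.

### Spike detection

Upward crossings of 0 mV separated by ≥ 1 ms; firing rate over the window
after discarding the first 20 % of the run; `blocked` means no spikes in
the window while mean V sits above V_t (depolarised but silent). All three
thresholds are configurable; they are operational definitions, not
physiology.

## 6. Bifurcation analysis

Brute-force continuation sweeps: for each current level (grid default
0…110 µA/cm², step 1.0 in the shipped analyses; 0.25 available), integrate
500 ms settle + 500 ms analysis window starting from the previous level's
final state, record the window's voltage extrema, call a level oscillating
when the excursion exceeds 10 mV. The offset current is the largest
oscillating level on the up-sweep. Bistability = a contiguous run of at
least three grid points where the up- and down-sweep masks disagree
(span > one grid step); ties in offset currents within one grid step are
flagged rather than silently ordered. No Hopf/SNIC classification or
Floquet analysis is attempted; all claims rest on orderings and
presence/absence of hysteresis, which are robust to the sweep approach.

## 7. What the model reproduces, and what it does not

With the committed parameterisation the package reproduces, from the
printed parameter table alone:

* **High-input behaviour** (I = 45): WT blocked at both temperatures (WT37
  at a fixed point; WT40 with a ~27 mV subthreshold oscillation and zero
  spikes), variant firing at both, with larger spike amplitude at 40 °C
  (~82 vs ~61 mV).
* **Offset ordering**: 33.5 (WT37) < 49.5 (WT40) < 69.0 (AV37) < 101.5
  (AV40) — the 40 °C variant tolerates by far the highest input before
  depolarisation block.
* **Bistability collapse**: WT37 bistable (interval ≈ 30–33.5), AV40
  monostable; bistable widths non-increasing across WT37 → WT40 → AV37 →
  AV40.
* **f–I ordering**: the 40 °C variant has the lowest firing rate at matched
  mid-range stimuli; wild-type rates grow at least as fast as variant rates.

Two published qualitative claims do **not** hold under the printed
parameters, and the acceptance tests report them honestly as failures:

* *All four conditions firing at the printed low input 0.2.* Onset here is
  SNIC-like, so rheobase is fixed by the steady-state I–V curve alone
  (independent of every time constant): its local maximum gives ≈ 0 (WT37),
  0.24 (WT40), 0.38 (AV37), 0.23 (AV40) µA/cm² at V_t = −65, and
  0.20/0.23/0.19 even at the printed V_t values. Three conditions sit just
  above 0.2, and no admissible re-reading (V_t, τ compositions, a global
  current rescale) brings all four below it without breaking the high-input
  pattern. Only WT37 fires at 0.2 in this implementation.
* *Hysteresis in both WT conditions.* WT40's offset is supercritical (no
  hysteresis at 0.25-unit resolution) under every parameter reading
  examined; only WT37 is bistable.

## 8. Problem sizes used in the shipped analyses

Parameter recovery uses 20 seeds per protocol at 1 % noise; the type-I-error
simulation uses 1000 null datasets (8 cells/group, 2 genotypes × 3
temperatures) and the power simulation 200 datasets at 10 cells/group with
a 0.3 mV/°C slope difference; single runs are 1500 ms; bifurcation sweeps
use a 1.0-step grid over 0–110 with 500+500 ms per level. These sizes keep
the full test suite and the acceptance script at a few minutes on one CPU
while leaving every reported ordering several grid steps clear of its
decision boundary.

## 9. Known limitations

* Single-compartment, two-current neuron: no M-current, no synaptic drive,
  no noise, no morphology; temperature enters only through the condition
  parameter sets.
* The channel stage's statistics assume Gaussian residuals and per-cell
  independence, mirroring the published design.
* The bifurcation analysis detects attractor coexistence only at the sweep
  timescale (500 ms per level); extremely slow switching would be missed.
* The generator's free-form kinetics (bell τ curves, one slow gate) are a
  stand-in, not a markov-model of NaV1.1; only steady-state parameters and
  recovery time constants are asserted against it.
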