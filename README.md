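# scn1a_dynamics

Voltage-clamp gating analysis and Boltzmann-reparameterised Hodgkin–Huxley
modelling of NaV1.1 (*SCN1A*) channel variants, built around a
temperature-sensitive epilepsy variant (A1273V) characterised at 37 °C and
40 °C.

The package is aimed at ion-channel biophysicists and computational
neurophysiologists who want a tested, end-to-end path from patch-clamp-style
sweep data to neuronal dynamics:

1. **Channel stage** — synthesise (or read) whole-cell Na⁺-current sweeps
   under the three standard protocols (activation, steady-state fast
   inactivation, recovery from inactivation), extract peaks and kinetics,
   and fit the field's standard models:

   - Boltzmann gating curves `x_∞(V) = 1/(1 + exp(−(V − V½)/s))` for
     conductance–voltage and availability relations,
   - single-exponential open-state inactivation decay,
   - double-exponential recovery `f(t) = c + A_f(1−e^{−t/τ_f}) + A_s(1−e^{−t/τ_s})`,
   - the two-factor linear model `value ~ genotype × temperature`
     (genotype nominal, temperature continuous) whose interaction F-test is
     the test for genotype differences in temperature sensitivity.

2. **Neuron stage** — a regular-spiking cortical Hodgkin–Huxley model

   `C·dV/dt = I_stim − g_L(V−E_L) − g_Na·m³h·(V−E_Na) − g_K·n⁴·(V−E_K)`

   with the sodium steady states `m_∞`, `h_∞` replaced by Boltzmann curves
   carrying measured condition parameters (WT/A1273V × 37/40 °C), while
   `n` and all time constants come from Traub-type rate functions.
   Stimulus-sweep bifurcation analysis locates the oscillation-offset
   current (depolarisation block) per condition and classifies the
   transition as monostable or bistable (hysteresis between up- and
   down-sweeps).

`docs/methods.md` documents the models, the V_t calibration, all numerical
choices, and exactly which published qualitative claims the printed
parameter set does and does not reproduce.

## Worked example

```python
from scn1a_dynamics import load_condition, simulate, detect_spikes, fit_baseline_gating
from scn1a_dynamics.io import VT_CALIBRATED

m, h = fit_baseline_gating(VT_CALIBRATED)
print(f"baseline fit at V_t={VT_CALIBRATED}: V_2m={m.v_half:.2f} mV, s_m={m.slope:.2f}, "
      f"V_2h={h.v_half:.2f} mV, s_h={h.slope:.2f}")
for label in ("WT37", "WT40", "AV37", "AV40"):
    p = load_condition(label)
    sim = simulate(p, 45.0, duration_ms=1500.0, dt_ms=0.02, method="rk4")
    train = detect_spikes(sim, v_t=p.v_t)
    print(f"{label}: I=45 -> rate {train.rate_hz:5.1f} Hz, blocked={train.blocked}")
```

prints

```
baseline fit at V_t=-65.0: V_2m=-39.03 mV, s_m=7.41, V_2h=-43.32 mV, s_h=-4.04
WT37: I=45 -> rate   0.0 Hz, blocked=True
WT40: I=45 -> rate   0.0 Hz, blocked=True
AV37: I=45 -> rate 391.7 Hz, blocked=False
AV40: I=45 -> rate 371.7 Hz, blocked=False
```

The first line is the calibration that ties the cortical baseline model to
the WT-37 °C gating row (fitting Boltzmann curves to the baseline
steady-state gating gives back the WT37 midpoints and slopes). The
simulation block shows the high-input divergence: at a strong stimulus the
wild-type neuron enters depolarisation block (depolarised but silent, rate
0) at both temperatures, while the variant keeps firing — the modelled
mechanism by which the mutation resists the autoregulatory shutdown of
high-frequency firing, most strongly at 40 °C.

A command-line interface mirrors the library:

```bash
scn1a-dynamics synth --protocol activation --seed 1 --out act      # sweep CSV+JSON
scn1a-dynamics fit activation --in act --out fits.json             # Boltzmann fit
scn1a-dynamics simulate --condition AV40 --istim 45 --out run.csv  # single run
scn1a-dynamics bifurcate --condition WT37 --out diagram.json       # up/down sweep
scn1a-dynamics run --seed 1 --out results/                         # full pipeline
```

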