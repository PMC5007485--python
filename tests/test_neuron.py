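"""Membrane model: derivatives, integration, spike detection, f-I curves."""

import math
from dataclasses import replace

import numpy as np
import pytest

from scn1a_dynamics import (
    derivatives,
    detect_spikes,
    fi_curve,
    load_condition,
    simulate,
    steady_state,
)
from scn1a_dynamics.neuron import SimResult


class TestDerivatives:
    def test_leak_only_equilibrium(self):
        p = replace(load_condition("WT37"), g_na=0.0, g_k=0.0)
        d = derivatives(steady_state(p, p.e_l), p, 0.0)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_gate_at_steady_state_has_zero_derivative(self):
        p = load_condition("WT37")
        s = steady_state(p, -50.0)
        d = derivatives(s, p, 0.0)
        np.testing.assert_allclose(d[1:], 0.0, atol=1e-12)

    def test_dvdt_matches_hand_computed_current_sum(self):
        """Independent arithmetic for the membrane equation at V=-65."""
        p = load_condition("WT37")
        v = -65.0
        m = 1.0 / (1.0 + math.exp(-(v + 39.0) / 7.4))
        h = 1.0 / (1.0 + math.exp(-(v + 43.3) / -4.0))
        n = 0.2
        i_l = 0.0205 * (v + 70.3)
        i_na = 56.0 * m**3 * h * (v - 50.0)
        i_k = 5.0 * n**4 * (v + 90.0)
        expected = (1.0 - i_l - i_na - i_k) / 1.0  # C = 0.010 uF/mm^2 = 1 uF/cm^2
        d = derivatives([v, m, h, n], p, 1.0)
        assert d[0] == pytest.approx(expected, rel=1e-12)


class TestSimulate:
    def test_zero_input_rests_near_leak_reversal(self):
        p = load_condition("WT40")
        sim = simulate(p, 0.0, duration_ms=500.0, method="rk4", dt_ms=0.02)
        train = detect_spikes(sim, v_t=p.v_t)
        assert train.rate_hz == 0.0
        assert abs(sim.v[-1] - p.e_l) < 5.0

    def test_low_input_wt37_fires_repetitively(self):
        p = load_condition("WT37")
        sim = simulate(p, 0.2, duration_ms=1500.0, method="rk4", dt_ms=0.02)
        train = detect_spikes(sim, v_t=p.v_t)
        assert len(train.spike_times_ms) >= 10
        assert not train.blocked

    def test_high_input_wt37_is_blocked(self):
        p = load_condition("WT37")
        sim = simulate(p, 45.0, duration_ms=1500.0, method="rk4", dt_ms=0.02)
        train = detect_spikes(sim, v_t=p.v_t)
        assert train.rate_hz == 0.0
        assert train.blocked

    def test_adaptive_and_rk4_agree_on_spike_count(self):
        p = load_condition("AV37")
        kwargs = dict(i_stim=45.0, duration_ms=300.0)
        a = simulate(p, method="adaptive", dt_ms=0.05, **kwargs)
        b = simulate(p, method="rk4", dt_ms=0.02, **kwargs)
        na = len(detect_spikes(a, v_t=p.v_t).spike_times_ms)
        nb = len(detect_spikes(b, v_t=p.v_t).spike_times_ms)
        assert na == nb

    def test_rk4_is_bitwise_reproducible(self):
        p = load_condition("AV40")
        a = simulate(p, 45.0, 200.0, 0.02, method="rk4")
        b = simulate(p, 45.0, 200.0, 0.02, method="rk4")
        np.testing.assert_array_equal(a.v, b.v)

    @pytest.mark.parametrize("label", ["WT37", "WT40", "AV37", "AV40"])
    @pytest.mark.parametrize("i_stim", [0.2, 45.0])
    def test_gates_bounded_on_standard_runs(self, label, i_stim):
        p = load_condition(label)
        sim = simulate(p, i_stim, duration_ms=600.0, method="rk4", dt_ms=0.02)
        for g in (sim.m, sim.h, sim.n):
            assert g.min() >= 0.0 and g.max() <= 1.0


class TestDetectSpikes:
    @staticmethod
    def _as_sim(t, v):
        return SimResult(
            time_ms=t, v=v, m=np.zeros_like(v), h=np.zeros_like(v),
            n=np.zeros_like(v), i_stim=0.0, params_label="fixture", dt_ms=t[1] - t[0],
        )

    def test_constant_hyperpolarised_trace(self):
        t = np.arange(0, 1000.0, 0.1)
        train = detect_spikes(self._as_sim(t, np.full_like(t, -70.0)), v_t=-65.0)
        assert train.rate_hz == 0.0 and not train.blocked

    def test_ten_spike_waveform_counted(self):
        t = np.arange(0, 1000.0, 0.1)
        v = np.full_like(t, -70.0)
        for k in range(10):
            centre = 905.0 + 10.0 * k  # inside the analysis window
            v[(t > centre - 0.5) & (t < centre + 0.5)] = 30.0
        train = detect_spikes(self._as_sim(t, v), v_t=-65.0)
        assert len(train.spike_times_ms) == 10

    def test_depolarised_plateau_flags_block(self):
        t = np.arange(0, 1000.0, 0.1)
        train = detect_spikes(self._as_sim(t, np.full_like(t, -20.0)), v_t=-65.0)
        assert train.blocked

    def test_refractory_merges_double_crossings(self):
        t = np.arange(0, 1000.0, 0.1)
        v = np.full_like(t, -70.0)
        # two crossings 0.3 ms apart -> one spike
        v[5000] = 10.0
        v[5003] = 10.0
        train = detect_spikes(self._as_sim(t, v), v_t=-65.0)
        assert len(train.spike_times_ms) == 1


class TestFICurve:
    def test_leak_only_neuron_never_fires(self):
        # currents bounded so the passive potential I/g_L stays subthreshold
        p = replace(load_condition("WT37"), g_na=0.0, g_k=0.0)
        rates = fi_curve(p, np.linspace(0.0, 1.0, 6), duration_ms=300.0)
        np.testing.assert_array_equal(rates, 0.0)

    def test_unsorted_grid_rejected(self):
        p = load_condition("WT37")
        with pytest.raises(ValueError):
            fi_curve(p, [1.0, 0.5])

    def test_rates_nondecreasing_at_low_currents(self):
        """Below depolarisation block the f-I curve rises monotonically."""
        p = load_condition("WT37")
        grid = np.linspace(0.5, 10.0, 8)
        rates = fi_curve(p, grid, duration_ms=400.0)
        assert rates[0] > 0
        assert np.all(np.diff(rates) >= -1e-9)
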