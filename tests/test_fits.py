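"""Channel-fit operations against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scn1a_dynamics import (
    BoltzmannParams,
    TrueChannelParams,
    boltzmann_value,
    fit_boltzmann,
    fit_recovery,
    fit_single_exp_decay,
    generate_sweepset,
    peak_currents,
    time_to_half_peak,
)
from scn1a_dynamics.fits import (
    CellMeasurement,
    conductance_curve,
    estimate_reversal,
    holm_adjust,
    interaction_test,
)
from scn1a_dynamics.io import SweepSet
from scn1a_dynamics.synth import gate_steady_states, gate_time_constants


class TestBoltzmannValue:
    def test_midpoint(self):
        assert boltzmann_value(-39.0, BoltzmannParams(-39.0, 7.4)) == pytest.approx(0.5)

    def test_quarter_point_closed_form(self):
        # V = V_half + s*ln(3) solves 1/(1+exp(-(V-Vh)/s)) = 0.75
        v = -39.0 + 7.4 * math.log(3.0)
        assert boltzmann_value(v, BoltzmannParams(-39.0, 7.4)) == pytest.approx(0.75)

    def test_falling_limit(self):
        assert boltzmann_value(1e3, BoltzmannParams(-43.3, -4.0)) == pytest.approx(0.0, abs=1e-12)


class TestPeakCurrents:
    def test_single_sample_peak(self, protocols):
        proto = protocols["activation"]
        traces = np.zeros((proto.n_sweeps, 100))
        traces[:, 50] = -5.0
        sweeps = SweepSet(0.05, traces, proto, 37.0, "x")
        np.testing.assert_array_equal(peak_currents(sweeps), -5.0)

    def test_blank_longer_than_sweep_rejected(self, truth, protocols):
        sweeps = generate_sweepset(truth, protocols["activation"], seed=0)
        with pytest.raises(ValueError, match="blank"):
            peak_currents(sweeps, blank_ms=1e5)

    def test_noiseless_peak_matches_gate_product_oracle(self, truth, protocols):
        """Peak equals g*m^3*h*s*(V-E_rev) evaluated at the trace argmax."""
        sweeps = generate_sweepset(truth, protocols["activation"], noise_sd=0.0, seed=0)
        peaks = peak_currents(sweeps)
        k = int(np.argmin(peaks))
        v = sweeps.protocol.step_voltages[k]
        trace = sweeps.traces[k]
        t_star = np.argmax(np.abs(trace)) * sweeps.dt_ms
        # closed-form gates at t_star from holding steady state
        m0, h0, s0 = gate_steady_states(truth, -90.0)
        mi, hi, si = gate_steady_states(truth, v)
        tm, th, ts = gate_time_constants(truth, v)
        m = mi + (m0 - mi) * math.exp(-t_star / tm)
        h = hi + (h0 - hi) * math.exp(-t_star / th)
        s = si + (s0 - si) * math.exp(-t_star / ts)
        expected = truth.g_max * m**3 * h * s * (v - truth.e_rev)
        assert peaks[k] == pytest.approx(expected, rel=1e-9)


class TestTimeToHalfPeak:
    def test_linear_ramp(self):
        trace = np.linspace(0.0, -1.0, 201)  # 2 ms at dt=0.01
        assert time_to_half_peak(trace, 0.01) == pytest.approx(1.0, abs=1e-9)

    def test_interpolation_matches_oversampled_oracle(self, truth, protocols):
        sweeps = generate_sweepset(truth, protocols["activation"], noise_sd=0.0, seed=0)
        fine = generate_sweepset(
            truth, protocols["activation"], noise_sd=0.0, seed=0, dt=0.005
        )
        k = int(np.argmin(peak_currents(sweeps)))
        coarse = time_to_half_peak(sweeps.traces[k], sweeps.dt_ms)
        oracle = time_to_half_peak(fine.traces[k], fine.dt_ms)
        assert coarse == pytest.approx(oracle, abs=0.05)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            time_to_half_peak(np.zeros(100), 0.05)


class TestConductanceCurve:
    def test_ohms_law_arithmetic(self):
        v, i, g = conductance_curve([-1.0], [0.0], v_rev=50.0)
        assert g[0] == pytest.approx(1.0)  # normalised
        assert (-1.0) / (0.0 - 50.0) == pytest.approx(0.02)

    def test_point_at_reversal_dropped(self):
        v, i, g = conductance_curve([-1.0, 0.0, 0.5], [0.0, 50.0, 60.0], v_rev=50.0)
        assert 50.0 not in v and len(v) == 2

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            conductance_curve([0.0], [50.0], v_rev=50.0)

    def test_normalized_g_matches_generator_profile(self, truth, protocols):
        """Noiseless G(V) tracks the steady-state conductance Boltzmann."""
        sweeps = generate_sweepset(truth, protocols["activation"], noise_sd=0.0, seed=0)
        peaks = peak_currents(sweeps)
        voltages = np.asarray(sweeps.protocol.step_voltages)
        v, _, g = conductance_curve(peaks, voltages, truth.e_rev)
        expected = truth.m_gate(v)
        expected = expected / expected[np.argmax(g)]
        # h decay before the peak sample costs a few percent at mid voltages
        assert np.max(np.abs(g - expected)[v >= -40]) < 0.12
        assert np.max(np.abs(g - expected)[v < -40]) < 0.01


class TestEstimateReversal:
    def test_zero_crossing_interpolated(self):
        v = np.array([-20.0, -10.0, 0.0, 10.0])
        i = np.array([-2.0, -1.0, -0.5, 0.5])
        assert estimate_reversal(i, v) == pytest.approx(5.0)

    def test_no_reversal_returns_none(self):
        assert estimate_reversal([-2.0, -1.0], [-20.0, 0.0]) is None


class TestFitBoltzmann:
    def test_exact_points_recovered(self):
        truth = BoltzmannParams(-43.3, -4.0)
        v = np.arange(-80.0, -10.0, 5.0)
        fit, diag = fit_boltzmann(v, truth(v), direction="falling")
        assert fit.v_half == pytest.approx(-43.3, abs=1e-6)
        assert fit.slope == pytest.approx(-4.0, abs=1e-6)
        assert diag["rms"] < 1e-8

    def test_flat_data_rejected(self):
        with pytest.raises(ValueError, match="range"):
            fit_boltzmann(np.arange(10.0), np.full(10, 0.5))

    @given(shift=st.floats(-40, 40))
    @settings(max_examples=25, deadline=None)
    def test_voltage_shift_equivariance(self, shift):
        """Shifting all voltages by c shifts V_half by c, slope unchanged."""
        truth = BoltzmannParams(-30.0, 6.5)
        v = np.arange(-70.0, 10.0, 4.0)
        rng = np.random.default_rng(11)
        y = truth(v) + rng.normal(0, 0.01, v.size)
        a, _ = fit_boltzmann(v, y, "rising")
        b, _ = fit_boltzmann(v + shift, y, "rising")
        assert b.v_half - a.v_half == pytest.approx(shift, abs=1e-6)
        assert b.slope == pytest.approx(a.slope, abs=1e-6)

    def test_noisy_ssfi_recovery_within_1mv(self):
        """15 prepulses, noise sd 0.02, 20 seeds: mean midpoint error < 1 mV."""
        truth = BoltzmannParams(-60.0, -6.0)
        v = np.linspace(-130.0, 10.0, 15)
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = truth(v) + rng.normal(0, 0.02, v.size)
            fit, _ = fit_boltzmann(v, y, "falling")
            errors.append(abs(fit.v_half - truth.v_half))
        assert np.mean(errors) < 1.0


class TestFitSingleExpDecay:
    def test_exact_exponential(self):
        t = np.arange(0, 10, 0.05)
        seg = -2.0 * np.exp(-t / 0.8)
        fit = fit_single_exp_decay(seg, 0.05, voltage=0.0)
        assert fit.tau == pytest.approx(0.8, rel=1e-6)

    def test_two_exponential_gives_intermediate_tau(self):
        t = np.arange(0, 20, 0.05)
        seg = -(0.5 * np.exp(-t / 0.5) + 0.5 * np.exp(-t / 4.0))
        fit = fit_single_exp_decay(seg, 0.05)
        assert 0.5 < fit.tau < 4.0

    def test_rising_segment_rejected(self):
        t = np.arange(0, 5, 0.05)
        with pytest.raises(ValueError):
            fit_single_exp_decay(-1.0 + 0.5 * t, 0.05)


class TestFitRecovery:
    def test_exact_double_exponential(self):
        t = np.array([0.5, 1, 2, 4, 8, 16, 32, 64, 128, 256, 512.0])
        f = 0.6 * (1 - np.exp(-t / 2.0)) + 0.35 * (1 - np.exp(-t / 50.0))
        fit = fit_recovery(f, t)
        assert not fit.single_exp_fallback
        assert fit.tau_fast == pytest.approx(2.0, abs=1e-4)
        assert fit.tau_slow == pytest.approx(50.0, abs=1e-3)
        assert fit.a_fast == pytest.approx(0.6, abs=1e-4)
        assert fit.a_slow == pytest.approx(0.35, abs=1e-4)

    def test_single_exponential_data_sets_fallback(self):
        t = np.array([0.5, 1, 2, 4, 8, 16, 32, 64, 128, 256, 512.0])
        f = 1.0 - np.exp(-t / 5.0)
        fit = fit_recovery(f, t)
        assert fit.single_exp_fallback
        assert fit.tau_fast == pytest.approx(5.0, rel=0.01)

    def test_amplitudes_sum_to_asymptote_on_noiseless_data(self):
        t = np.array([0.5, 1, 2, 4, 8, 16, 32, 64, 128, 256, 512.0])
        f = 0.05 + 0.55 * (1 - np.exp(-t / 3.0)) + 0.4 * (1 - np.exp(-t / 60.0))
        fit = fit_recovery(f, t)
        assert fit.offset + fit.a_fast + fit.a_slow == pytest.approx(1.0, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_recovery([0.1, 0.5, 0.9], [1.0, 10.0, 100.0])


def _interaction_f_oracle(genotype, temperature, value):
    """F-statistic for the interaction via explicit normal equations."""
    g = np.asarray(genotype, dtype=float)
    t = np.asarray(temperature, dtype=float)
    y = np.asarray(value, dtype=float)
    X_full = np.column_stack([np.ones_like(y), g, t, g * t])
    X_red = X_full[:, :3]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_f, rss_r = rss(X_full), rss(X_red)
    df_den = len(y) - X_full.shape[1]
    return (rss_r - rss_f) / (rss_f / df_den)


class TestInteractionTest:
    @staticmethod
    def _measurements(values, genos=("WT", "MUT"), temps=(37.0, 40.0)):
        out, k = [], 0
        for g in genos:
            for t in temps:
                for _ in range(len(values) // (len(genos) * len(temps))):
                    out.append(CellMeasurement(f"c{k}", g, t, values[k]))
                    k += 1
        return out

    def test_equal_slopes_zero_noise_gives_zero_f(self):
        # value = 2*T regardless of genotype, plus a genotype offset
        vals = [74.0, 74.0, 80.0, 80.0, 75.0, 75.0, 81.0, 81.0]
        res = interaction_test(self._measurements(vals))
        assert res.f_interaction == pytest.approx(0.0, abs=1e-18)
        assert res.refit_without_interaction

    def test_f_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        vals = list(rng.normal(0, 1, 8))
        res = interaction_test(self._measurements(vals))
        g = [0, 0, 1, 1, 0, 0, 1, 1]
        t = [37, 37, 40, 40, 37, 37, 40, 40]
        # measurement order from _measurements: WT37,WT40,MUT37,MUT40 x2
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        t = [37, 37, 40, 40, 37, 37, 40, 40]
        f_oracle = _interaction_f_oracle(g, t, vals)
        assert res.f_interaction == pytest.approx(f_oracle, rel=1e-9)
        assert res.df_num == 1 and res.df_den == 4

    def test_strong_interaction_is_detected_and_not_refit(self):
        rng = np.random.default_rng(9)
        ms = []
        for gi, g in enumerate(("WT", "MUT")):
            for t in (32.0, 37.0, 40.0):
                for c in range(6):
                    v = 0.5 * t + gi * 2.0 * t + rng.normal(0, 1.0)
                    ms.append(CellMeasurement(f"{g}{t}{c}", g, t, v))
        res = interaction_test(ms)
        assert res.p_interaction < 0.05
        assert not res.refit_without_interaction

    def test_single_temperature_rejected(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValueError):
            interaction_test(self._measurements(vals, temps=(37.0,)))


def test_holm_adjustment_is_monotone_and_conservative():
    p = [0.001, 0.04, 0.2, 0.8]
    adj = holm_adjust(p)
    assert np.all(adj >= np.asarray(p))
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)
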