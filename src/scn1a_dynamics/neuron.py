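"""Boltzmann-reparameterised Hodgkin-Huxley cortical neuron model.

Membrane equation (mV, ms, uA/cm^2, mS/cm^2, uF/cm^2)::

    C dV/dt = I_stim - g_L (V - E_L) - g_Na m^3 h (V - E_Na) - g_K n^4 (V - E_K)

Gates relax first-order toward voltage-dependent steady states,
``dx/dt = (x_inf(V) - x) / tau_x(V)``.  The sodium steady states ``m_inf``
and ``h_inf`` are Boltzmann sigmoids carrying the condition-specific
experimental parameters; the delayed-rectifier ``n`` and all time constants
come from the baseline Traub-type rate functions (``tau_x = 1/(alpha_x +
beta_x)``).  The fast-inactivation time constant is evaluated with the
condition's ``T_off`` added to the membrane potential inside the h rate
functions -- an additive voltage offset of the h kinetics that implements
the condition-dependent shift of fast-inactivation time constants along
the voltage axis.

Two integrators are provided: an adaptive stiff-capable method (LSODA,
rtol 1e-8 / atol 1e-10) for single runs, and a fixed-step RK4 core
(optionally numba-compiled) whose bitwise reproducibility makes it the
workhorse for stimulus sweeps and f-I curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from scn1a_dynamics.io import NeuronParams
from scn1a_dynamics.conditions import baseline_rate_functions

__all__ = [
    "SimResult",
    "SpikeTrain",
    "derivatives",
    "steady_state",
    "simulate",
    "detect_spikes",
    "fi_curve",
]

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 1.0
TRANSIENT_DISCARD_FRAC = 0.2


@dataclass
class SimResult:
    """Membrane-potential and gate trajectories from one stimulation run."""

    time_ms: np.ndarray
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    i_stim: float
    params_label: str
    dt_ms: float

    def final_state(self) -> np.ndarray:
        return np.array([self.v[-1], self.m[-1], self.h[-1], self.n[-1]])


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times and firing rate extracted from a simulation."""

    spike_times_ms: tuple
    rate_hz: float
    blocked: bool

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times_ms)
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise ValueError("spike times must be increasing")
        if self.rate_hz < 0:
            raise ValueError("rate must be >= 0")


def _params_tuple(p: NeuronParams) -> tuple:
    return (
        p.v_t,
        p.m_gate.v_half, p.m_gate.slope,
        p.h_gate.v_half, p.h_gate.slope,
        p.t_off,
        p.g_l, p.g_k, p.g_na,
        p.e_l, p.e_k, p.e_na,
        1.0 / p.c_uf_per_cm2,
    )


def _rhs_scalar(v, m, h, n, I,
                v_t, v2m, sm, v2h, sh, t_off,
                g_l, g_k, g_na, e_l, e_k, e_na, c_inv):
    # Traub-type rates; removable singularities via series limits
    x = v - v_t
    u = -(x - 13.0)
    am = 0.32 * (4.0 if abs(u) < 1e-7 else u / math.expm1(u / 4.0) if u / 4.0 < 700.0 else 0.0)
    u = x - 40.0
    bm = 0.28 * (5.0 if abs(u) < 1e-7 else u / math.expm1(u / 5.0) if u / 5.0 < 700.0 else 0.0)
    u = -(x - 15.0)
    an = 0.032 * (5.0 if abs(u) < 1e-7 else u / math.expm1(u / 5.0) if u / 5.0 < 700.0 else 0.0)
    bn = 0.5 * math.exp(-(x - 10.0) / 40.0)
    # h rates with the condition's additive voltage offset
    xh = (v + t_off) - v_t
    ah = 0.128 * math.exp(-(xh - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(xh - 40.0) / 5.0))

    m_inf = 1.0 / (1.0 + math.exp(-(v - v2m) / sm))
    h_inf = 1.0 / (1.0 + math.exp(-(v - v2h) / sh))
    n_inf = an / (an + bn)
    tau_m = 1.0 / (am + bm)
    tau_h = 1.0 / (ah + bh)
    tau_n = 1.0 / (an + bn)

    dv = (I - g_l * (v - e_l) - g_na * m * m * m * h * (v - e_na)
          - g_k * n * n * n * n * (v - e_k)) * c_inv
    return (dv, (m_inf - m) / tau_m, (h_inf - h) / tau_h, (n_inf - n) / tau_n)


def _rk4_core(y, n_steps, dt, stride, I, pt, out):
    v, m, h, n = y[0], y[1], y[2], y[3]
    (v_t, v2m, sm, v2h, sh, t_off,
     g_l, g_k, g_na, e_l, e_k, e_na, c_inv) = pt
    j = 0
    out[0, 0], out[1, 0], out[2, 0], out[3, 0] = v, m, h, n
    for i in range(n_steps):
        k1 = _rhs_scalar(v, m, h, n, I, v_t, v2m, sm, v2h, sh, t_off,
                         g_l, g_k, g_na, e_l, e_k, e_na, c_inv)
        k2 = _rhs_scalar(v + 0.5 * dt * k1[0], m + 0.5 * dt * k1[1],
                         h + 0.5 * dt * k1[2], n + 0.5 * dt * k1[3], I,
                         v_t, v2m, sm, v2h, sh, t_off,
                         g_l, g_k, g_na, e_l, e_k, e_na, c_inv)
        k3 = _rhs_scalar(v + 0.5 * dt * k2[0], m + 0.5 * dt * k2[1],
                         h + 0.5 * dt * k2[2], n + 0.5 * dt * k2[3], I,
                         v_t, v2m, sm, v2h, sh, t_off,
                         g_l, g_k, g_na, e_l, e_k, e_na, c_inv)
        k4 = _rhs_scalar(v + dt * k3[0], m + dt * k3[1],
                         h + dt * k3[2], n + dt * k3[3], I,
                         v_t, v2m, sm, v2h, sh, t_off,
                         g_l, g_k, g_na, e_l, e_k, e_na, c_inv)
        v = v + dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        m = m + dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        h = h + dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        n = n + dt / 6.0 * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])
        # first-order relaxation cannot leave [0,1]; trim RK4 rounding spill
        if m < 0.0:
            m = 0.0
        elif m > 1.0:
            m = 1.0
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        if (i + 1) % stride == 0:
            j += 1
            out[0, j], out[1, j], out[2, j], out[3, j] = v, m, h, n
    return j


try:  # optional acceleration; identical arithmetic either way
    import numba

    _rhs_scalar = numba.njit(cache=True)(_rhs_scalar)
    _rk4_core = numba.njit(cache=True)(_rk4_core)
except ImportError:  # pragma: no cover
    pass


def derivatives(state, params: NeuronParams, i_stim: float):
    """Time derivative of ``(V, m, h, n)`` -- a pure function of the state."""
    v, m, h, n = (float(s) for s in state)
    return np.array(_rhs_scalar(v, m, h, n, float(i_stim), *_params_tuple(params)))


def steady_state(params: NeuronParams, v: float) -> np.ndarray:
    """State vector with all gates at their steady-state values for ``v``."""
    _, _, _, _, an, bn = baseline_rate_functions(np.asarray(v), params.v_t)
    return np.array(
        [v, params.m_gate(v), params.h_gate(v), float(an / (an + bn))]
    )


def simulate(
    params: NeuronParams,
    i_stim: float,
    duration_ms: float = 1500.0,
    dt_ms: float = 0.05,
    initial_state=None,
    method: str = "adaptive",
) -> SimResult:
    """Integrate the membrane model under a constant stimulus current.

    ``method='adaptive'`` uses LSODA (rtol 1e-8, atol 1e-10, max step
    0.5 ms) sampled on the ``dt_ms`` grid; ``method='rk4'`` takes fixed
    RK4 steps of exactly ``dt_ms`` and is bitwise reproducible.  The
    default initial state is rest at ``E_L`` with gates at their steady
    states there.
    """
    if initial_state is None:
        y0 = steady_state(params, params.e_l)
    else:
        y0 = np.asarray(initial_state, dtype=float)
    pt = _params_tuple(params)

    if method == "rk4":
        n_steps = int(round(duration_ms / dt_ms))
        out = np.empty((4, n_steps + 1))
        _rk4_core(y0, n_steps, float(dt_ms), 1, float(i_stim), pt, out)
        t = np.arange(n_steps + 1) * dt_ms
        v, m, h, n = out
    elif method == "adaptive":
        def rhs(t, y):
            return _rhs_scalar(y[0], y[1], y[2], y[3], float(i_stim), *pt)

        t = np.arange(0.0, duration_ms + dt_ms / 2.0, dt_ms)
        sol = solve_ivp(
            rhs, (0.0, t[-1]), y0, method="LSODA",
            rtol=1e-8, atol=1e-10, max_step=0.5, t_eval=t,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(
                f"integration failed for {params.label} at I={i_stim}: {sol.message}"
            )
        v, m, h, n = sol.y
    else:
        raise ValueError("method must be 'adaptive' or 'rk4'")

    if not np.all(np.isfinite(v)):
        raise RuntimeError(f"non-finite membrane potential ({params.label}, I={i_stim})")
    return SimResult(
        time_ms=t, v=v, m=m, h=h, n=n,
        i_stim=float(i_stim), params_label=params.label, dt_ms=float(dt_ms),
    )


def detect_spikes(
    sim: SimResult,
    threshold_mv: float = SPIKE_THRESHOLD_MV,
    refractory_ms: float = SPIKE_REFRACTORY_MS,
    discard_frac: float = TRANSIENT_DISCARD_FRAC,
    v_t: float | None = None,
) -> SpikeTrain:
    """Spike times, firing rate and depolarisation-block flag.

    Spikes are upward crossings of ``threshold_mv`` separated by at least
    ``refractory_ms``; the rate is computed over the window remaining after
    discarding the first ``discard_frac`` of the run.  ``blocked`` is set
    when the window contains no spikes yet the mean potential sits above
    the rate-function threshold ``v_t`` -- i.e. the membrane is depolarised
    but silent.
    """
    t, v = sim.time_ms, sim.v
    up = np.nonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))[0]
    times = []
    for k in up:
        frac = (threshold_mv - v[k]) / (v[k + 1] - v[k])
        tc = t[k] + frac * (t[k + 1] - t[k])
        if not times or tc - times[-1] >= refractory_ms:
            times.append(float(tc))
    t0 = t[0] + discard_frac * (t[-1] - t[0])
    in_window = [tt for tt in times if tt >= t0]
    window_ms = t[-1] - t0
    rate = len(in_window) / window_ms * 1000.0 if window_ms > 0 else 0.0
    if v_t is None:
        v_t = -65.0
    blocked = (len(in_window) == 0) and (float(np.mean(v[t >= t0])) > v_t)
    return SpikeTrain(spike_times_ms=tuple(times), rate_hz=rate, blocked=blocked)


def fi_curve(
    params: NeuronParams,
    i_grid,
    duration_ms: float = 500.0,
    dt_ms: float = 0.02,
    method: str = "rk4",
) -> np.ndarray:
    """Firing rate (Hz) at each stimulus in ``i_grid``, with continuation.

    Each run starts from the previous run's final state, mimicking a slow
    stimulus ramp; the first run starts from rest at ``E_L``.
    """
    i_grid = np.asarray(i_grid, dtype=float)
    if i_grid.size > 1 and not np.all(np.diff(i_grid) > 0):
        raise ValueError("i_grid must be strictly increasing")
    rates = np.empty(i_grid.size)
    state = None
    for k, i_stim in enumerate(i_grid):
        sim = simulate(params, i_stim, duration_ms, dt_ms, initial_state=state, method=method)
        rates[k] = detect_spikes(sim, v_t=params.v_t).rate_hz
        state = sim.final_state()
    return rates
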