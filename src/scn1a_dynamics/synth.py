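"""Synthetic whole-cell voltage-clamp sweep generator with known ground truth.

Currents follow a three-gate channel model,

    ``I(t) = g_max * m(t)^3 * h(t) * s(t) * (V - E_rev)``,

where ``m`` is activation, ``h`` fast inactivation and ``s`` a small slow
inactivation component.  Each gate relaxes exponentially toward its
voltage-dependent steady state with a bell-shaped time constant.  The
activation gate relaxes toward the cube root of the ground-truth
conductance Boltzmann, so the steady-state conductance ``m^3`` follows the
stated midpoint/slope -- the convention under which conductance-voltage
midpoints are reported.  The slow gate engages only at depolarised
potentials (where availability is already near zero) and is what gives
recovery from a long conditioning pulse its double-exponential time
course; it leaves activation and availability curves essentially
untouched.

Within a constant-voltage segment the relaxation is evaluated in closed
form, so gate endpoints are independent of the sampling interval and the
only error in a noiseless sweep is floating-point rounding.  Gaussian
noise is added per sample; identical seeds give identical traces.

Series resistance, space-clamp and capacitive artefacts are not modelled:
traces stand for recordings after standard P/4 leak subtraction.
Temperature and genotype conditions are emulated by supplying different
ground-truth parameter sets, not by rate scaling inside the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from scn1a_dynamics.io import SweepSet, TrueChannelParams, VoltageProtocol

__all__ = [
    "GateTrajectory",
    "default_protocols",
    "tau_bell",
    "gate_steady_states",
    "gate_time_constants",
    "simulate_gates",
    "generate_sweepset",
]

#: Default sampling interval, ms (20 kHz, comfortably above the 5 kHz
#: low-pass corner of typical recordings).
DEFAULT_DT_MS = 0.05


@dataclass(frozen=True)
class GateTrajectory:
    """Gate values on a shared time grid (activation, fast and slow inactivation)."""

    time_ms: np.ndarray
    m: np.ndarray
    h: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        for x in (self.m, self.h, self.s):
            if np.any((x < -1e-12) | (x > 1 + 1e-12)):
                raise ValueError("gate values must lie in [0, 1]")


def default_protocols() -> dict:
    """The three standard pulse protocols.

    * ``activation``: 20 ms steps, -100 to +60 mV in 10 mV increments
      (17 sweeps), holding -90 mV.
    * ``ssfi``: 200 ms prepulses, -130 to +10 mV in 10 mV increments,
      followed by a 20 ms test pulse to 0 mV.
    * ``recovery``: 200 ms conditioning at 0 mV, recovery at -90 mV over a
      log-spaced ladder of 12 durations (0.5 to 512 ms), 20 ms test pulse
      to 0 mV.  The ladder is a package choice; published work does not
      list one.
    """
    activation = VoltageProtocol(
        kind="activation",
        holding_mv=-90.0,
        step_voltages=tuple(np.arange(-100.0, 60.0 + 1e-9, 10.0)),
        step_duration_ms=20.0,
    )
    ssfi = VoltageProtocol(
        kind="ssfi",
        holding_mv=-90.0,
        step_voltages=tuple(np.arange(-130.0, 10.0 + 1e-9, 10.0)),
        step_duration_ms=20.0,
        prepulse_duration_ms=200.0,
        test_voltage_mv=0.0,
    )
    recovery = VoltageProtocol(
        kind="recovery",
        holding_mv=-90.0,
        step_duration_ms=20.0,
        conditioning_duration_ms=200.0,
        recovery_times_ms=tuple(0.5 * 2.0 ** np.arange(0, 10.5, 10 / 11.0)),
        test_voltage_mv=0.0,
    )
    return {"activation": activation, "ssfi": ssfi, "recovery": recovery}


def tau_bell(v, v_half: float, slope: float, tau_base: float, tau_floor: float):
    """Bell-shaped gate time constant, ms.

    ``tau(V) = tau_base / cosh((V - v_half) / (2 * slope)) + tau_floor``;
    peaked at the gate midpoint and saturating at ``tau_floor`` far from it.
    """
    v = np.asarray(v, dtype=float)
    out = tau_base / np.cosh((v - v_half) / (2.0 * slope)) + tau_floor
    return float(out) if out.ndim == 0 else out


def gate_steady_states(truth: TrueChannelParams, v: float) -> tuple[float, float, float]:
    """Steady-state ``(m, h, s)`` at voltage ``v``.

    ``m`` targets the cube root of the conductance Boltzmann; ``s`` is the
    available fraction ``1 - a_slow * slow_inactivated(V)``.
    """
    m_inf = float(truth.m_gate(v)) ** (1.0 / 3.0)
    h_inf = float(truth.h_gate(v))
    s_inf = 1.0 - truth.a_slow * float(truth.s_gate(v))
    return m_inf, h_inf, s_inf


def gate_time_constants(truth: TrueChannelParams, v: float) -> tuple[float, float, float]:
    """Gate time constants ``(tau_m, tau_h, tau_s)`` (ms) at voltage ``v``."""
    tau_m = tau_bell(v, truth.m_gate.v_half, truth.m_gate.slope, truth.tau_m_base, truth.tau_m_floor)
    tau_h = tau_bell(v, truth.h_gate.v_half, truth.h_gate.slope, truth.tau_h_base, truth.tau_h_floor)
    tau_s = tau_bell(v, truth.s_gate.v_half, truth.s_gate.slope, truth.tau_s_base, truth.tau_s_floor)
    return float(tau_m), float(tau_h), float(tau_s)


def _segment_relax(x0: float, x_inf: float, tau: float, t) -> np.ndarray:
    return x_inf + (x0 - x_inf) * np.exp(-np.asarray(t) / tau)


def simulate_gates(
    truth: TrueChannelParams,
    voltage_schedule,
    dt: float = DEFAULT_DT_MS,
    x0: tuple | None = None,
) -> GateTrajectory:
    """Integrate the gates through a piecewise-constant voltage schedule.

    Parameters
    ----------
    truth
        Ground-truth channel parameters.
    voltage_schedule
        Sequence of ``(voltage_mV, duration_ms)`` segments.
    dt
        Sample interval of the returned trajectory, ms.
    x0
        Optional initial ``(m, h, s)``; defaults to the steady state at the
        first segment's voltage.

    Within each segment, ``x(t) = x_inf + (x0 - x_inf) * exp(-t / tau(V))``
    exactly; segment endpoints therefore satisfy the semigroup property
    (two consecutive segments at the same voltage equal one merged
    segment) and do not depend on ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    segments = [(float(v), float(d)) for v, d in voltage_schedule]
    if not segments or any(d <= 0 for _, d in segments):
        raise ValueError("voltage_schedule must contain segments of positive duration")

    if x0 is None:
        state = list(gate_steady_states(truth, segments[0][0]))
    else:
        state = [float(x) for x in x0]

    times, samples = [], [[], [], []]
    t_origin = 0.0
    for v, dur in segments:
        taus = gate_time_constants(truth, v)
        if any(not np.isfinite(tau) or tau <= 0 for tau in taus):
            raise ValueError("non-finite or non-positive gate time constant")
        infs = gate_steady_states(truth, v)
        t_local = np.arange(0.0, dur, dt)
        times.append(t_origin + t_local)
        for k in range(3):
            samples[k].append(_segment_relax(state[k], infs[k], taus[k], t_local))
            state[k] = float(_segment_relax(state[k], infs[k], taus[k], dur))
        t_origin += dur

    return GateTrajectory(
        time_ms=np.concatenate(times),
        m=np.concatenate(samples[0]),
        h=np.concatenate(samples[1]),
        s=np.concatenate(samples[2]),
    )


def _sweep_schedules(protocol: VoltageProtocol, hold_ms: float):
    """Per-sweep piecewise-constant schedules plus the recorded window.

    Returns a list of ``(schedule, record_start_ms, record_voltage)``.
    Only the analysed window is recorded: the step itself for activation
    sweeps, the test pulse for ssfi and recovery sweeps.
    """
    out = []
    if protocol.kind == "activation":
        for v in protocol.step_voltages:
            sched = [(protocol.holding_mv, hold_ms), (v, protocol.step_duration_ms)]
            out.append((sched, hold_ms, v))
    elif protocol.kind == "ssfi":
        for v in protocol.step_voltages:
            sched = [
                (protocol.holding_mv, hold_ms),
                (v, protocol.prepulse_duration_ms),
                (protocol.test_voltage_mv, protocol.step_duration_ms),
            ]
            out.append(
                (sched, hold_ms + protocol.prepulse_duration_ms, protocol.test_voltage_mv)
            )
    else:  # recovery
        for trec in protocol.recovery_times_ms:
            trec = max(trec, 1e-9)
            sched = [
                (protocol.holding_mv, hold_ms),
                (0.0, protocol.conditioning_duration_ms),
                (protocol.holding_mv, trec),
                (protocol.test_voltage_mv, protocol.step_duration_ms),
            ]
            rec_start = hold_ms + protocol.conditioning_duration_ms + trec
            out.append((sched, rec_start, protocol.test_voltage_mv))
    return out


def generate_sweepset(
    truth: TrueChannelParams,
    protocol: VoltageProtocol,
    dt: float = DEFAULT_DT_MS,
    noise_sd: float | None = None,
    seed: int = 0,
    temperature_c: float = 37.0,
    condition_label: str = "synthetic",
    hold_ms: float = 50.0,
) -> SweepSet:
    """Generate a voltage-clamp sweep set with ground truth attached.

    ``noise_sd`` is the standard deviation of i.i.d. Gaussian current noise
    in nA; ``None`` uses the ground-truth value.  With ``noise_sd = 0`` the
    traces are fully deterministic, and a step held at the reversal
    potential produces exactly zero current at every sample.  Each sweep
    starts from the steady state at the holding potential after ``hold_ms``
    of settling.
    """
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = truth.noise_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    traces = []
    x_hold = gate_steady_states(truth, protocol.holding_mv)
    for sched, rec_start, v_rec in _sweep_schedules(protocol, hold_ms):
        gates = simulate_gates(truth, sched, dt=dt, x0=x_hold)
        total = sum(d for _, d in sched)
        sel = (gates.time_ms >= rec_start - 1e-9) & (gates.time_ms < total - 1e-9)
        i = (
            truth.g_max
            * gates.m[sel] ** 3
            * gates.h[sel]
            * gates.s[sel]
            * (v_rec - truth.e_rev)
        )
        traces.append(i)

    n = min(len(t) for t in traces)
    traces = np.vstack([t[:n] for t in traces])
    if noise_sd > 0:
        traces = traces + rng.normal(0.0, noise_sd, size=traces.shape)

    return SweepSet(
        dt_ms=dt,
        traces=traces,
        protocol=protocol,
        temperature_c=temperature_c,
        condition_label=condition_label,
        ground_truth=replace(truth, noise_sd=float(noise_sd)),
    )
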