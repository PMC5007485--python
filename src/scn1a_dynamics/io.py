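"""Domain types for sweeps, fits and model parameters, plus disk round-tripping.

Unit conventions
----------------
The clamp stage works in mV, ms and nA throughout.  The neuron stage stores
the published parameter numerals verbatim (see :data:`TABLE1_CONDITIONS`);
the simulator converts the membrane capacitance to uF/cm^2 (the printed
0.010 uF/mm^2 equals exactly 1 uF/cm^2) and treats conductance densities in
mS/cm^2 and stimulus currents in uA/cm^2, which together with mV and ms form
a dimensionally consistent Hodgkin-Huxley unit scheme.

Trace files are delimited text (CSV, header ``time_ms,sweep_000,...``);
metadata and condition configurations are JSON with explicit unit strings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VoltageProtocol",
    "SweepSet",
    "BoltzmannParams",
    "ActivationFit",
    "InactivationFit",
    "RecoveryFit",
    "DecayFit",
    "NeuronParams",
    "TrueChannelParams",
    "read_sweepset",
    "write_sweepset",
    "load_condition",
    "write_condition",
    "read_condition",
    "CONDITION_LABELS",
    "VT_CALIBRATED",
]

#: Rate-function threshold offset (mV) used by every condition preset.
#:
#: Calibrated once so that Boltzmann fits to the baseline cortical-neuron
#: steady-state gating curves reproduce the WT 37 degC row (V_2m = -39.0 mV,
#: V_2h = -43.3 mV); see :func:`scn1a_dynamics.conditions.calibrate_vt`.
#: Published parameter listings variously give -55 or -60 mV, neither of
#: which is consistent with the published WT37 Boltzmann midpoints under
#: Traub-type kinetics; the calibrated value is committed instead.
VT_CALIBRATED = -65.0

CONDITION_LABELS = ("WT37", "WT40", "AV37", "AV40")


class SweepIOError(ValueError):
    """Raised for malformed or inconsistent sweep/metadata files."""


@dataclass(frozen=True)
class BoltzmannParams:
    """Midpoint and slope of a sigmoid gating curve.

    The convention is ``x_inf(V) = 1 / (1 + exp(-(V - v_half) / slope))``:
    a positive slope gives an increasing sigmoid (activation), a negative
    slope a decreasing one (availability / fast inactivation).
    """

    v_half: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope == 0 or not math.isfinite(self.slope):
            raise ValueError("Boltzmann slope must be finite and non-zero")
        if not math.isfinite(self.v_half):
            raise ValueError("Boltzmann midpoint must be finite")

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        out = 1.0 / (1.0 + np.exp(-(v - self.v_half) / self.slope))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class VoltageProtocol:
    """One of the three whole-cell pulse protocols.

    ``activation``: 20 ms steps from the holding potential to each voltage in
    ``step_voltages``.  ``ssfi``: a long prepulse to each step voltage
    followed by a fixed test pulse.  ``recovery``: a fixed conditioning
    depolarisation, a recovery interval at the holding potential of varying
    length, then a test pulse.
    """

    kind: str
    holding_mv: float
    step_voltages: tuple = ()
    step_duration_ms: float = 20.0
    prepulse_duration_ms: Optional[float] = None
    conditioning_duration_ms: Optional[float] = None
    recovery_times_ms: Optional[tuple] = None
    test_voltage_mv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "ssfi", "recovery"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        object.__setattr__(self, "step_voltages", tuple(float(v) for v in self.step_voltages))
        if self.recovery_times_ms is not None:
            object.__setattr__(
                self, "recovery_times_ms", tuple(float(t) for t in self.recovery_times_ms)
            )
        if self.step_duration_ms <= 0:
            raise ValueError("step_duration_ms must be > 0")
        if self.kind in ("activation", "ssfi"):
            sv = np.asarray(self.step_voltages)
            if sv.size < 2 or not np.all(np.diff(sv) > 0):
                raise ValueError("step_voltages must be strictly increasing")
        if self.kind == "ssfi":
            if self.prepulse_duration_ms is None or self.prepulse_duration_ms <= 0:
                raise ValueError("ssfi protocol requires prepulse_duration_ms > 0")
            if self.test_voltage_mv is None:
                raise ValueError("ssfi protocol requires a test voltage")
        if self.kind == "recovery":
            if self.conditioning_duration_ms is None or self.conditioning_duration_ms <= 0:
                raise ValueError("recovery protocol requires conditioning_duration_ms > 0")
            rt = np.asarray(self.recovery_times_ms if self.recovery_times_ms else ())
            if rt.size < 2 or not np.all(np.diff(rt) > 0) or rt[0] < 0:
                raise ValueError("recovery_times_ms must be non-negative, strictly increasing")
            if self.test_voltage_mv is None:
                raise ValueError("recovery protocol requires a test voltage")

    @property
    def n_sweeps(self) -> int:
        if self.kind == "recovery":
            return len(self.recovery_times_ms)
        return len(self.step_voltages)


@dataclass(frozen=True)
class TrueChannelParams:
    """Ground-truth channel parameters for the synthetic sweep generator.

    ``g_max`` is a whole-cell maximal conductance in uS so that currents in
    nA follow from driving forces in mV.  ``m_gate`` parameterises the
    steady-state *conductance* curve: the activation gate relaxes toward
    the cube root of this Boltzmann, so that the m^3 conductance profile --
    the quantity a conductance-voltage analysis actually measures -- follows
    the stated midpoint and slope.  ``h_gate`` is fast inactivation
    (availability).  ``s_gate`` is a small slow-inactivation component:
    an increasing Boltzmann giving the slow-inactivated fraction, engaged
    only at depolarised potentials and weighted by ``a_slow``; it is what
    makes recovery from a long conditioning pulse double-exponential.
    ``tau_*_base``/``tau_*_floor`` parameterise bell-shaped
    voltage-dependent time constants (ms) peaking at each gate's midpoint.
    """

    g_max: float = 0.05
    e_rev: float = 45.0
    m_gate: BoltzmannParams = field(default_factory=lambda: BoltzmannParams(-20.0, 7.0))
    h_gate: BoltzmannParams = field(default_factory=lambda: BoltzmannParams(-60.0, -6.0))
    s_gate: BoltzmannParams = field(default_factory=lambda: BoltzmannParams(-30.0, 6.0))
    a_slow: float = 0.35
    tau_m_base: float = 0.04
    tau_m_floor: float = 0.01
    tau_h_base: float = 12.0
    tau_h_floor: float = 5.0
    tau_s_base: float = 150.0
    tau_s_floor: float = 60.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise ValueError("g_max must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.a_slow < 1.0:
            raise ValueError("a_slow must lie in [0, 1)")
        if self.m_gate.slope <= 0:
            raise ValueError("m gate must be an increasing sigmoid (slope > 0)")
        if self.h_gate.slope >= 0:
            raise ValueError("h gate must be a decreasing sigmoid (slope < 0)")
        if self.s_gate.slope <= 0:
            raise ValueError("s gate is the slow-inactivated fraction (slope > 0)")
        for tau in (
            self.tau_m_base, self.tau_m_floor, self.tau_h_base,
            self.tau_h_floor, self.tau_s_base, self.tau_s_floor,
        ):
            if tau <= 0:
                raise ValueError("time-constant parameters must be > 0")


@dataclass
class SweepSet:
    """A stack of current traces on a shared time base with protocol metadata."""

    dt_ms: float
    traces: np.ndarray  # (n_sweeps, n_samples), nA
    protocol: VoltageProtocol
    temperature_c: float
    condition_label: str
    ground_truth: Optional[TrueChannelParams] = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if self.traces.ndim != 2 or self.traces.size == 0:
            raise ValueError("traces must be a non-empty 2-D array")
        if self.traces.shape[0] != self.protocol.n_sweeps:
            raise SweepIOError(
                f"trace count {self.traces.shape[0]} does not match protocol "
                f"({self.protocol.n_sweeps} sweeps expected)"
            )

    @property
    def n_sweeps(self) -> int:
        return self.traces.shape[0]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.traces.shape[1]) * self.dt_ms


@dataclass(frozen=True)
class ActivationFit:
    """Conductance-voltage analysis of an activation sweep set."""

    v_rev: float
    voltages: tuple
    peak_currents: tuple  # nA, signed
    normalized_g: tuple  # in [0, 1], max exactly 1
    boltzmann: BoltzmannParams

    def __post_init__(self) -> None:
        if self.boltzmann.slope <= 0:
            raise ValueError("activation Boltzmann slope must be positive")


@dataclass(frozen=True)
class InactivationFit:
    """Steady-state fast inactivation (availability) analysis."""

    voltages: tuple
    normalized_i: tuple
    boltzmann: BoltzmannParams

    def __post_init__(self) -> None:
        if self.boltzmann.slope >= 0:
            raise ValueError("availability Boltzmann slope must be negative")


@dataclass(frozen=True)
class RecoveryFit:
    """Double-exponential fit of recovery from fast inactivation.

    ``fraction(t) = offset + a_fast * (1 - exp(-t / tau_fast))
    + a_slow * (1 - exp(-t / tau_slow))`` with ``tau_fast < tau_slow``.
    ``single_exp_fallback`` flags data that did not support two separable
    components.
    """

    tau_fast: float
    tau_slow: float
    a_fast: float
    a_slow: float
    offset: float
    single_exp_fallback: bool = False

    def __post_init__(self) -> None:
        if not (self.tau_fast > 0 and self.tau_slow > 0):
            raise ValueError("recovery time constants must be > 0")
        if not self.single_exp_fallback and not self.tau_fast < self.tau_slow:
            raise ValueError("tau_fast must be < tau_slow")
        if self.a_fast < 0 or self.a_slow < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential open-state inactivation time constant at one voltage."""

    voltage: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("decay tau must be > 0")


@dataclass(frozen=True)
class NeuronParams:
    """One full Hodgkin-Huxley condition parameterisation.

    Numerals are stored exactly as published: ``c_m`` in uF/mm^2, ``g_l``,
    ``g_k`` and ``g_na`` in mS/cm^2, reversal potentials in mV.  ``v_t`` is
    the rate-function threshold offset (mV) shared by every preset
    (:data:`VT_CALIBRATED`).  ``t_off`` is an additive voltage offset (mV)
    applied inside the fast-inactivation rate functions only, capturing
    condition-dependent changes in the h-gate time constant.
    """

    label: str
    c_m: float = 0.010
    g_l: float = 0.0205
    g_k: float = 5.0
    g_na: float = 56.0
    e_l: float = -70.3
    e_k: float = -90.0
    e_na: float = 50.0
    v_t: float = VT_CALIBRATED
    m_gate: BoltzmannParams = field(default_factory=lambda: BoltzmannParams(-39.0, 7.4))
    h_gate: BoltzmannParams = field(default_factory=lambda: BoltzmannParams(-43.3, -4.0))
    t_off: float = 0.0

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("capacitance must be > 0")
        for g in (self.g_l, self.g_k, self.g_na):
            if g < 0:
                raise ValueError("conductance densities must be >= 0")

    @property
    def c_uf_per_cm2(self) -> float:
        """Membrane capacitance converted to uF/cm^2 (exact: x100)."""
        return self.c_m * 100.0


# Published condition-specific gating values (s_m, s_h, V_2m, V_2h, T_off).
# The AV40 inactivation slope is printed with a positive sign; it is stored
# negative here so that availability decreases with depolarisation, in line
# with every other condition and with the measured availability curves.
_TABLE1_GATING = {
    "WT37": (7.4, -4.0, -39.0, -43.3, 0.0),
    "WT40": (6.6, -3.4, -32.5, -45.2, 1.9),
    "AV37": (6.1, -3.4, -33.1, -41.0, -2.4),
    "AV40": (7.6, -3.8, -29.1, -31.6, -11.7),
}

TABLE1_CONDITIONS = {
    label: NeuronParams(
        label=label,
        m_gate=BoltzmannParams(v2m, sm),
        h_gate=BoltzmannParams(v2h, sh),
        t_off=toff,
    )
    for label, (sm, sh, v2m, v2h, toff) in _TABLE1_GATING.items()
}


def load_condition(label: str) -> NeuronParams:
    """Return the preset :class:`NeuronParams` for one of the four conditions.

    Parameters are the published values verbatim (with the AV40 inactivation
    slope sign-corrected, see :data:`TABLE1_CONDITIONS`).
    """
    try:
        return TABLE1_CONDITIONS[label]
    except KeyError:
        raise KeyError(
            f"unknown condition {label!r}; expected one of {CONDITION_LABELS}"
        ) from None


# ---------------------------------------------------------------------------
# serialisation helpers


def _boltz_to_dict(b: BoltzmannParams) -> dict:
    return {"v_half_mV": b.v_half, "slope_mV": b.slope}


def _boltz_from_dict(d: dict) -> BoltzmannParams:
    return BoltzmannParams(float(d["v_half_mV"]), float(d["slope_mV"]))


def _truth_to_dict(t: TrueChannelParams) -> dict:
    d = asdict(t)
    for gate in ("m_gate", "h_gate", "s_gate"):
        d[gate] = _boltz_to_dict(getattr(t, gate))
    return d


def _truth_from_dict(d: dict) -> TrueChannelParams:
    d = dict(d)
    for gate in ("m_gate", "h_gate", "s_gate"):
        d[gate] = _boltz_from_dict(d[gate])
    return TrueChannelParams(**d)


def _protocol_to_dict(p: VoltageProtocol) -> dict:
    d = asdict(p)
    d["step_voltages"] = list(p.step_voltages)
    if p.recovery_times_ms is not None:
        d["recovery_times_ms"] = list(p.recovery_times_ms)
    return d


def _protocol_from_dict(d: dict) -> VoltageProtocol:
    d = dict(d)
    d["step_voltages"] = tuple(d.get("step_voltages") or ())
    if d.get("recovery_times_ms") is not None:
        d["recovery_times_ms"] = tuple(d["recovery_times_ms"])
    return VoltageProtocol(**d)


def write_sweepset(sweeps: SweepSet, path_traces, path_meta) -> None:
    """Write a sweep set as a trace CSV plus a metadata JSON document.

    The round trip through :func:`read_sweepset` preserves traces to full
    stored precision (17 significant digits) and all metadata including the
    optional ground-truth block.
    """
    if sweeps.traces.size == 0:
        raise ValueError("refusing to write an empty trace matrix")
    path_traces = Path(path_traces)
    path_meta = Path(path_meta)
    cols = {"time_ms": sweeps.time_ms}
    for i, tr in enumerate(sweeps.traces):
        cols[f"sweep_{i:03d}"] = tr
    pd.DataFrame(cols).to_csv(path_traces, index=False, float_format="%.17g")
    meta = {
        "protocol": _protocol_to_dict(sweeps.protocol),
        "temperature_C": sweeps.temperature_c,
        "condition": sweeps.condition_label,
        "dt_ms": sweeps.dt_ms,
        "units": {"time": "ms", "current": "nA", "voltage": "mV"},
    }
    if sweeps.ground_truth is not None:
        meta["ground_truth"] = _truth_to_dict(sweeps.ground_truth)
    path_meta.write_text(json.dumps(meta, indent=2))


def read_sweepset(path_traces, path_meta) -> SweepSet:
    """Read and validate a sweep set written by :func:`write_sweepset`."""
    path_traces = Path(path_traces)
    path_meta = Path(path_meta)
    try:
        meta = json.loads(path_meta.read_text())
    except json.JSONDecodeError as e:
        raise SweepIOError(f"metadata {path_meta} is not valid JSON: {e}") from e
    df = pd.read_csv(path_traces, float_precision="round_trip")
    if "time_ms" not in df.columns:
        raise SweepIOError(f"{path_traces} is missing the time_ms column")
    sweep_cols = [c for c in df.columns if c.startswith("sweep_")]
    if not sweep_cols:
        raise SweepIOError(f"{path_traces} contains no sweep_* columns")
    t = df["time_ms"].to_numpy()
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise SweepIOError("time_ms column must be strictly increasing")
    protocol = _protocol_from_dict(meta["protocol"])
    traces = df[sweep_cols].to_numpy().T
    if traces.shape[0] != protocol.n_sweeps:
        raise SweepIOError(
            f"metadata names {protocol.n_sweeps} sweeps but trace file has "
            f"{traces.shape[0]} columns"
        )
    truth = meta.get("ground_truth")
    return SweepSet(
        dt_ms=float(meta["dt_ms"]),
        traces=traces,
        protocol=protocol,
        temperature_c=float(meta["temperature_C"]),
        condition_label=str(meta["condition"]),
        ground_truth=_truth_from_dict(truth) if truth else None,
    )


def write_condition(params: NeuronParams, path) -> None:
    """Write a condition configuration JSON mirroring the published field names."""
    doc = {
        "label": params.label,
        "C": params.c_m,
        "gL": params.g_l,
        "gK": params.g_k,
        "gNa": params.g_na,
        "EL": params.e_l,
        "EK": params.e_k,
        "ENa": params.e_na,
        "Vt": params.v_t,
        "sm": params.m_gate.slope,
        "sh": params.h_gate.slope,
        "V2m": params.m_gate.v_half,
        "V2h": params.h_gate.v_half,
        "Toff": params.t_off,
        "units": {
            "C": "uF/mm^2",
            "g": "mS/cm^2",
            "E": "mV",
            "V": "mV",
            "note": "AV40 sh stored negative (decreasing availability); "
            "Vt is the calibrated rate-function threshold",
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_condition(path) -> NeuronParams:
    d = json.loads(Path(path).read_text())
    return NeuronParams(
        label=str(d["label"]),
        c_m=float(d["C"]),
        g_l=float(d["gL"]),
        g_k=float(d["gK"]),
        g_na=float(d["gNa"]),
        e_l=float(d["EL"]),
        e_k=float(d["EK"]),
        e_na=float(d["ENa"]),
        v_t=float(d["Vt"]),
        m_gate=BoltzmannParams(float(d["V2m"]), float(d["sm"])),
        h_gate=BoltzmannParams(float(d["V2h"]), float(d["sh"])),
        t_off=float(d["Toff"]),
    )
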