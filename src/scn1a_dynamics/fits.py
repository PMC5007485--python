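"""Voltage-clamp analysis: peaks, kinetics, Boltzmann/exponential fits, statistics.

This module implements the analysis stage applied to activation, steady-state
fast inactivation (SSFI) and recovery sweep sets:

* peak currents and conductance via Ohm's law with the observed reversal,
* Boltzmann fits of conductance-voltage and availability curves,
* single-exponential fits of open-state inactivation decay,
* double-exponential fits of recovery from fast inactivation,
* a two-factor (genotype x temperature) linear model whose interaction term
  tests for genotype differences in temperature sensitivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from scn1a_dynamics.io import (
    ActivationFit,
    BoltzmannParams,
    DecayFit,
    InactivationFit,
    RecoveryFit,
    SweepSet,
)

__all__ = [
    "boltzmann_value",
    "peak_currents",
    "time_to_half_peak",
    "estimate_reversal",
    "conductance_curve",
    "fit_boltzmann",
    "fit_single_exp_decay",
    "fit_recovery",
    "fit_activation",
    "fit_ssfi",
    "recovery_fractions",
    "CellMeasurement",
    "InteractionTestResult",
    "interaction_test",
    "holm_adjust",
]

logger = logging.getLogger(__name__)

#: Default blank window (ms) excluded from peak searches; stands in for the
#: residual capacitive transient at the step onset.
DEFAULT_BLANK_MS = 0.2

#: Step voltages closer than this (mV) to the reversal potential are dropped
#: from conductance curves (division by a vanishing driving force).
REVERSAL_EXCLUSION_MV = 2.0


def boltzmann_value(v, params: BoltzmannParams):
    """Evaluate the Boltzmann sigmoid ``1 / (1 + exp(-(V - V_half)/slope))``."""
    return params(v)


#: Boxcar width (ms) applied by the sweep-level fit wrappers before peak
#: extraction, mirroring the acquisition low-pass filter.  The raw
#: :func:`peak_currents` default applies no smoothing.
DEFAULT_SMOOTH_MS = 0.25


def peak_currents(
    sweeps: SweepSet, blank_ms: float = DEFAULT_BLANK_MS, smooth_ms: float = 0.0
) -> np.ndarray:
    """Signed peak current per sweep (sample of maximal magnitude).

    The first ``blank_ms`` of each sweep is excluded from the search.
    ``smooth_ms > 0`` applies a centred boxcar of that width first, which
    suppresses the upward bias that sample-wise peak picking suffers on
    noisy traces.
    """
    n_blank = int(round(blank_ms / sweeps.dt_ms))
    if n_blank >= sweeps.traces.shape[1]:
        raise ValueError(
            f"blank window {blank_ms} ms covers the whole sweep "
            f"({sweeps.traces.shape[1]} samples at {sweeps.dt_ms} ms)"
        )
    traces = sweeps.traces
    w = int(round(smooth_ms / sweeps.dt_ms))
    if w > 1:
        kernel = np.ones(w) / w
        traces = np.apply_along_axis(
            lambda x: np.convolve(x, kernel, mode="same"), 1, traces
        )
    window = traces[:, n_blank:]
    if not np.any(window):
        raise ValueError("all-zero sweep set has no defined peaks")
    idx = np.argmax(np.abs(window), axis=1)
    return window[np.arange(window.shape[0]), idx]


def time_to_half_peak(trace: np.ndarray, dt: float) -> float:
    """First time (ms) at which |I| reaches half its peak, interpolated.

    The crossing is located on the rising phase (before the peak sample) and
    refined by linear interpolation between the bracketing samples.
    """
    a = np.abs(np.asarray(trace, dtype=float))
    if a.size < 2 or np.all(a == 0):
        raise ValueError("trace has no defined extremum")
    ip = int(np.argmax(a))
    half = 0.5 * a[ip]
    if a[0] >= half:
        return 0.0
    above = np.nonzero(a[: ip + 1] >= half)[0]
    if above.size == 0:
        raise ValueError("trace never crosses half-peak before its peak")
    k = int(above[0])
    frac = (half - a[k - 1]) / (a[k] - a[k - 1])
    return (k - 1 + frac) * dt


def estimate_reversal(peaks, voltages) -> float | None:
    """Reversal potential from the zero crossing of the peak I-V relation.

    Linear interpolation between the last inward (negative) and first
    outward (positive) point; ``None`` when the I-V relation does not
    change sign.
    """
    peaks = np.asarray(peaks, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    sign_change = np.nonzero((peaks[:-1] < 0) & (peaks[1:] >= 0))[0]
    if sign_change.size == 0:
        return None
    k = int(sign_change[-1])
    if peaks[k + 1] == peaks[k]:
        return float(voltages[k + 1])
    frac = -peaks[k] / (peaks[k + 1] - peaks[k])
    return float(voltages[k] + frac * (voltages[k + 1] - voltages[k]))


def conductance_curve(
    peaks,
    voltages,
    v_rev: float,
    exclusion_tol_mv: float = REVERSAL_EXCLUSION_MV,
):
    """Normalised conductance ``G(V) = I_peak / (V - V_rev)``, max scaled to 1.

    Points within ``exclusion_tol_mv`` of the reversal potential are dropped
    (logged), since the driving force vanishes there.

    Returns ``(kept_voltages, kept_peaks, normalized_g)``.
    """
    peaks = np.asarray(peaks, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    keep = np.abs(voltages - v_rev) > exclusion_tol_mv
    if not np.any(keep):
        raise ValueError("all points excluded by the reversal-potential tolerance")
    dropped = voltages[~keep]
    if dropped.size:
        logger.warning(
            "dropping %d point(s) within %.1f mV of V_rev=%.1f mV: %s",
            dropped.size, exclusion_tol_mv, v_rev, dropped.tolist(),
        )
    g = peaks[keep] / (voltages[keep] - v_rev)
    gmax = np.max(g)
    if gmax <= 0:
        raise ValueError("conductances are non-positive; check the reversal potential")
    return voltages[keep], peaks[keep], g / gmax


def _boltz(v, v_half, slope):
    return 1.0 / (1.0 + np.exp(-(v - v_half) / slope))


def fit_boltzmann(x, y, direction: str = "rising") -> tuple[BoltzmannParams, dict]:
    """Least-squares Boltzmann fit with the slope sign fixed by ``direction``.

    Requires at least 4 points whose values span a range of at least 0.2
    (anything flatter carries no information about the transition).  Returns
    the fitted parameters together with diagnostics (residual RMS, number of
    points).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a Boltzmann")
    if np.ptp(y) < 0.2:
        raise ValueError("y range < 0.2: data do not span the transition")

    # initial guess: midpoint where y crosses its half-range
    half = (y.min() + y.max()) / 2.0
    order = np.argsort(x)
    xo, yo = x[order], y[order]
    k = int(np.argmin(np.abs(yo - half)))
    v0 = xo[k]
    span = max(np.ptp(x) / 6.0, 1.0)
    s0 = span if direction == "rising" else -span

    if direction == "rising":
        bounds = ([x.min() - 100.0, 1e-3], [x.max() + 100.0, 200.0])
    else:
        bounds = ([x.min() - 100.0, -200.0], [x.max() + 100.0, -1e-3])
    popt, _ = curve_fit(
        _boltz, x, y, p0=[v0, s0], bounds=bounds, method="trf",
        xtol=1e-8, ftol=1e-8, gtol=1e-8, maxfev=10000,
    )
    resid = y - _boltz(x, *popt)
    params = BoltzmannParams(float(popt[0]), float(popt[1]))
    return params, {"rms": float(np.sqrt(np.mean(resid**2))), "n": int(x.size)}


def fit_single_exp_decay(segment: np.ndarray, dt: float, voltage: float = 0.0) -> DecayFit:
    """Fit ``I(t) = A exp(-t / tau) + C`` to a decaying current segment.

    The segment must start at the peak; a segment whose magnitude grows
    overall is rejected.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 4:
        raise ValueError("decay segment too short")
    t = np.arange(seg.size) * dt
    if np.abs(seg[-1]) >= np.abs(seg[0]) or np.abs(seg[0]) == 0:
        raise ValueError("segment does not decay from its initial peak")

    a0 = seg[0] - seg[-1]
    c0 = seg[-1]
    # crude tau guess: time to reach 1/e of the initial excursion
    target = c0 + a0 / np.e
    idx = np.nonzero(np.abs(seg - c0) <= np.abs(a0) / np.e)[0]
    tau0 = t[idx[0]] if idx.size else t[-1] / 3.0
    tau0 = max(tau0, dt)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    popt, _ = curve_fit(
        model, t, seg, p0=[a0, tau0, c0],
        bounds=([-np.inf, dt * 1e-3, -np.inf], [np.inf, t[-1] * 100.0, np.inf]),
        method="trf", xtol=1e-8, ftol=1e-8, maxfev=10000,
    )
    return DecayFit(voltage=float(voltage), tau=float(popt[1]))


def _double_exp(t, a_f, tau_f, a_s, tau_s, c):
    return c + a_f * (1.0 - np.exp(-t / tau_f)) + a_s * (1.0 - np.exp(-t / tau_s))


def fit_recovery(fractions, recovery_times) -> RecoveryFit:
    """Double-exponential fit of recovery fractions versus recovery time.

    ``f(t) = offset + A_fast (1 - exp(-t/tau_fast)) + A_slow (1 - exp(-t/tau_slow))``
    with ``tau_fast < tau_slow`` enforced by sorting.  Fitting uses
    trust-region least squares from three starting points.  When the two
    components are not separable (a vanishing amplitude or nearly equal time
    constants, as for intrinsically single-exponential data) the best
    single-exponential fit is returned with ``single_exp_fallback`` set.
    """
    f = np.asarray(fractions, dtype=float)
    t = np.asarray(recovery_times, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 recovery time points")
    tmin, tmax = t[t > 0].min(), t.max()

    starts = [
        (tmin, tmax / 4.0),
        (tmin * 4.0, tmax),
        (np.sqrt(tmin * tmax) / 3.0, np.sqrt(tmin * tmax) * 3.0),
    ]
    amp = max(np.ptp(f), 1e-6)
    best = None
    for tf0, ts0 in starts:
        try:
            popt, _ = curve_fit(
                _double_exp, t, f,
                p0=[0.6 * amp, tf0, 0.4 * amp, ts0, f.min()],
                bounds=([0.0, tmin * 1e-3, 0.0, tmin * 1e-3, -1.0],
                        [2.0, tmax * 100.0, 2.0, tmax * 100.0, 1.0]),
                method="trf", xtol=1e-10, ftol=1e-10, maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((f - _double_exp(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)

    def _single_fallback() -> RecoveryFit:
        def single(tt, a, tau, c):
            return c + a * (1.0 - np.exp(-tt / tau))

        popt, _ = curve_fit(
            single, t, f, p0=[amp, np.sqrt(tmin * tmax), f.min()],
            bounds=([0.0, tmin * 1e-3, -1.0], [2.0, tmax * 100.0, 1.0]),
            method="trf", maxfev=20000,
        )
        a, tau, c = popt
        return RecoveryFit(
            tau_fast=float(tau), tau_slow=float(tau * 1e3), a_fast=float(a),
            a_slow=0.0, offset=float(c), single_exp_fallback=True,
        )

    if best is None:
        return _single_fallback()

    a_f, tau_f, a_s, tau_s, c = best[0]
    if tau_f > tau_s:
        a_f, tau_f, a_s, tau_s = a_s, tau_s, a_f, tau_f
    total = a_f + a_s
    degenerate = (
        total <= 0
        or min(a_f, a_s) / total < 5e-3
        or tau_s / tau_f < 2.0
    )
    if degenerate:
        return _single_fallback()
    return RecoveryFit(
        tau_fast=float(tau_f), tau_slow=float(tau_s),
        a_fast=float(a_f), a_slow=float(a_s), offset=float(c),
    )


# ---------------------------------------------------------------------------
# sweep-set level conveniences


def _fit_boltzmann_free_amp(x, y, direction: str) -> BoltzmannParams:
    """Boltzmann fit with a free amplitude, ``A / (1 + exp(-(V-Vh)/s))``.

    Used for conductance curves: letting the plateau level float keeps
    noise-inflated saturation points from biasing the midpoint, matching
    how conductance-voltage relations are fit in practice.  Only midpoint
    and slope are returned; curves are still reported normalised to max 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def model(v, a, v_half, slope):
        return a / (1.0 + np.exp(-(v - v_half) / slope))

    p_unit, _ = fit_boltzmann(x, y, direction)
    lo_s, hi_s = (1e-3, 200.0) if direction == "rising" else (-200.0, -1e-3)
    popt, _ = curve_fit(
        model, x, y, p0=[1.0, p_unit.v_half, p_unit.slope],
        bounds=([0.1, x.min() - 100.0, lo_s], [10.0, x.max() + 100.0, hi_s]),
        method="trf", xtol=1e-8, ftol=1e-8, maxfev=10000,
    )
    return BoltzmannParams(float(popt[1]), float(popt[2]))


def fit_activation(
    sweeps: SweepSet,
    blank_ms: float = DEFAULT_BLANK_MS,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> ActivationFit:
    """Full conductance-voltage analysis of an activation sweep set.

    The reversal potential is estimated from the peak I-V zero crossing (the
    experimentally observed reversal); if the I-V relation never reverses the
    generator ground truth is used when available.
    """
    if sweeps.protocol.kind != "activation":
        raise ValueError("expected an activation-protocol sweep set")
    peaks = peak_currents(sweeps, blank_ms=blank_ms, smooth_ms=smooth_ms)
    voltages = np.asarray(sweeps.protocol.step_voltages)
    v_rev = estimate_reversal(peaks, voltages)
    if v_rev is None:
        if sweeps.ground_truth is not None:
            v_rev = sweeps.ground_truth.e_rev
            logger.warning("I-V relation does not reverse; using ground-truth E_rev")
        else:
            raise ValueError("cannot estimate a reversal potential from the I-V relation")
    v_kept, i_kept, g = conductance_curve(peaks, voltages, v_rev)
    boltz = _fit_boltzmann_free_amp(v_kept, g, direction="rising")
    return ActivationFit(
        v_rev=float(v_rev),
        voltages=tuple(v_kept),
        peak_currents=tuple(i_kept),
        normalized_g=tuple(g),
        boltzmann=boltz,
    )


def fit_ssfi(
    sweeps: SweepSet,
    blank_ms: float = DEFAULT_BLANK_MS,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> InactivationFit:
    """Availability curve from SSFI test-pulse currents, normalised to max 1."""
    if sweeps.protocol.kind != "ssfi":
        raise ValueError("expected an ssfi-protocol sweep set")
    peaks = peak_currents(sweeps, blank_ms=blank_ms, smooth_ms=smooth_ms)
    voltages = np.asarray(sweeps.protocol.step_voltages)
    mag = np.abs(peaks)
    norm = mag / mag.max()
    boltz, _ = fit_boltzmann(voltages, norm, direction="falling")
    return InactivationFit(
        voltages=tuple(voltages), normalized_i=tuple(norm), boltzmann=boltz
    )


def recovery_fractions(
    sweeps: SweepSet,
    blank_ms: float = DEFAULT_BLANK_MS,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> np.ndarray:
    """Recovered fraction per recovery interval (test peak / largest test peak)."""
    if sweeps.protocol.kind != "recovery":
        raise ValueError("expected a recovery-protocol sweep set")
    mag = np.abs(peak_currents(sweeps, blank_ms=blank_ms, smooth_ms=smooth_ms))
    return mag / mag.max()


# ---------------------------------------------------------------------------
# temperature-sensitivity statistics


@dataclass(frozen=True)
class CellMeasurement:
    """One per-cell measurement of a gating quantity (e.g. a Boltzmann midpoint)."""

    cell_id: str
    genotype: str
    temperature_c: float
    value: float

    def __post_init__(self) -> None:
        if self.temperature_c <= 0:
            raise ValueError("temperature must be positive (degC)")


@dataclass(frozen=True)
class InteractionTestResult:
    """Two-step test of genotype differences in temperature sensitivity.

    The full model ``value ~ genotype + temperature + genotype:temperature``
    (genotype nominal, temperature continuous) is compared against the
    additive model by an F-test of the interaction term.  When the
    interaction is not significant at ``alpha`` the additive model is refit
    and the genotype/temperature main effects are reported from it
    (``refit_without_interaction`` is then True).
    """

    f_interaction: float
    df_num: int
    df_den: int
    p_interaction: float
    refit_without_interaction: bool
    f_main_genotype: float
    p_main_genotype: float
    f_main_temperature: float
    p_main_temperature: float
    alpha: float = 0.05


def interaction_test(
    measurements: Iterable[CellMeasurement], alpha: float = 0.05
) -> InteractionTestResult:
    """Run the two-factor temperature-sensitivity analysis.

    Requires at least two genotypes, at least two temperatures, and more
    observations than full-model parameters.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        [
            {"genotype": m.genotype, "temperature": m.temperature_c, "value": m.value}
            for m in measurements
        ]
    )
    n_geno = df["genotype"].nunique()
    n_temp = df["temperature"].nunique()
    if n_geno < 2 or n_temp < 2:
        raise ValueError("need at least 2 genotypes and 2 temperatures")
    n_params_full = 2 * n_geno  # per-genotype intercept and slope
    if len(df) <= n_params_full:
        raise ValueError("need more observations than full-model parameters")

    full = smf.ols("value ~ C(genotype) * temperature", data=df).fit()
    additive = smf.ols("value ~ C(genotype) + temperature", data=df).fit()
    if full.df_resid <= 0 or np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("design is rank deficient")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp_tbl = anova_lm(additive, full)
    f_int = float(cmp_tbl["F"].iloc[1])
    p_int = float(cmp_tbl["Pr(>F)"].iloc[1])
    df_num = int(cmp_tbl["df_diff"].iloc[1])
    df_den = int(full.df_resid)
    # a perfect additive fit leaves both residual sums at rounding level,
    # where the F ratio is numerically meaningless: report no interaction
    tss = float(np.var(df["value"])) * len(df)
    if full.ssr <= 1e-12 * max(tss, 1.0) and additive.ssr <= 1e-12 * max(tss, 1.0):
        f_int, p_int = 0.0, 1.0
    if not np.isfinite(f_int):
        f_int, p_int = 0.0, 1.0

    refit = p_int >= alpha
    model_for_mains = additive if refit else full
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mains = anova_lm(model_for_mains, typ=2)
    f_geno = float(mains.loc["C(genotype)", "F"])
    p_geno = float(mains.loc["C(genotype)", "PR(>F)"])
    f_temp = float(mains.loc["temperature", "F"])
    p_temp = float(mains.loc["temperature", "PR(>F)"])

    return InteractionTestResult(
        f_interaction=f_int,
        df_num=df_num,
        df_den=df_den,
        p_interaction=min(max(p_int, 0.0), 1.0),
        refit_without_interaction=bool(refit),
        f_main_genotype=f_geno,
        p_main_genotype=p_geno,
        f_main_temperature=f_temp,
        p_main_temperature=p_temp,
        alpha=alpha,
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (for transparency alongside raw ones)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]
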