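"""Stimulus-sweep bifurcation analysis of oscillation offset and bistability.

Depolarisation block is characterised by sweeping the stimulus current up
and then down with continuation (each level starts from the previous
level's final state), recording steady-window voltage extrema at every
level.  A level "oscillates" when its voltage excursion exceeds an
amplitude threshold.  The largest oscillating current on the up-sweep is
the oscillation-offset current; hysteresis between the up and down masks
-- the spiking and blocked attractors coexisting over a current interval
-- marks a bistable (subcritical) offset bifurcation, while agreement
marks a monostable one.

Brute-force continuation sweeping is deliberate: it mirrors how such
diagrams are produced in practice, and the quantities of interest
(offset-current orderings, presence or absence of hysteresis) are robust
to it.  No formal bifurcation-type identification (Hopf vs SNIC) is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from scn1a_dynamics.io import NeuronParams
from scn1a_dynamics.neuron import simulate, steady_state

__all__ = ["BifurcationDiagram", "sweep", "classify", "compare_conditions"]

#: Voltage excursion (mV) above which a steady window counts as oscillating.
AMPLITUDE_THRESHOLD_MV = 10.0
DEFAULT_SETTLE_MS = 500.0
DEFAULT_WINDOW_MS = 500.0


@dataclass
class BifurcationDiagram:
    """Per-stimulus steady-window voltage extrema from up- and down-sweeps."""

    i_grid: np.ndarray
    up_extrema: np.ndarray  # (n, 2): V_min, V_max
    down_extrema: np.ndarray
    onset_current: Optional[float]
    offset_current: Optional[float]
    bistable: bool
    bistable_interval: tuple = ()
    amplitude_threshold_mv: float = AMPLITUDE_THRESHOLD_MV
    failed_points: tuple = ()

    def osc_mask(self, direction: str = "up") -> np.ndarray:
        ext = self.up_extrema if direction == "up" else self.down_extrema
        return (ext[:, 1] - ext[:, 0]) > self.amplitude_threshold_mv


def sweep(
    params: NeuronParams,
    i_grid,
    direction: str = "up",
    settle_ms: float = DEFAULT_SETTLE_MS,
    window_ms: float = DEFAULT_WINDOW_MS,
    dt_ms: float = 0.02,
    method: str = "rk4",
):
    """Continuation sweep over ``i_grid``; returns (extrema, failed_points).

    ``extrema[k]`` holds ``(V_min, V_max)`` over the analysis window at
    ``i_grid[k]`` (grid order, regardless of sweep direction).  The first
    level starts from rest at ``E_L``; every further level starts from the
    previous level's final state.  Integration failures leave NaN rows and
    are reported in ``failed_points`` rather than aborting the sweep.
    """
    i_grid = np.asarray(i_grid, dtype=float)
    if i_grid.size < 2 or not np.all(np.diff(i_grid) > 0):
        raise ValueError("i_grid must be strictly increasing")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")

    order = range(i_grid.size) if direction == "up" else range(i_grid.size - 1, -1, -1)
    extrema = np.full((i_grid.size, 2), np.nan)
    failed = []
    state = steady_state(params, params.e_l)
    duration = settle_ms + window_ms
    for k in order:
        try:
            sim = simulate(
                params, i_grid[k], duration_ms=duration, dt_ms=dt_ms,
                initial_state=state, method=method,
            )
        except RuntimeError:
            failed.append(float(i_grid[k]))
            continue
        win = sim.v[sim.time_ms >= settle_ms]
        extrema[k] = (win.min(), win.max())
        state = sim.final_state()
    return extrema, tuple(failed)


def classify(
    up_extrema: np.ndarray,
    down_extrema: np.ndarray,
    i_grid,
    amplitude_threshold_mv: float = AMPLITUDE_THRESHOLD_MV,
    failed_points: tuple = (),
) -> BifurcationDiagram:
    """Combine up/down sweep extrema into a classified diagram.

    The offset current is the largest oscillating level on the up-sweep and
    the onset current the smallest.  The diagram is bistable when a
    contiguous run of levels disagrees between the sweep directions over a
    current span wider than one grid step (at least three grid points);
    the classification is symmetric in sweep direction.
    """
    i_grid = np.asarray(i_grid, dtype=float)
    up_extrema = np.asarray(up_extrema, dtype=float)
    down_extrema = np.asarray(down_extrema, dtype=float)
    if up_extrema.shape != down_extrema.shape or up_extrema.shape[0] != i_grid.size:
        raise ValueError("up/down sweeps must share one grid")

    amp_up = up_extrema[:, 1] - up_extrema[:, 0]
    amp_dn = down_extrema[:, 1] - down_extrema[:, 0]
    osc_up = amp_up > amplitude_threshold_mv
    osc_dn = amp_dn > amplitude_threshold_mv

    onset = float(i_grid[osc_up][0]) if osc_up.any() else None
    offset = float(i_grid[osc_up][-1]) if osc_up.any() else None

    disagree = osc_up != osc_dn
    bistable = False
    interval: tuple = ()
    if disagree.any():
        # longest contiguous disagreement run
        best_start = best_len = 0
        run_start = None
        for k, d in enumerate(np.append(disagree, False)):
            if d and run_start is None:
                run_start = k
            elif not d and run_start is not None:
                if k - run_start > best_len:
                    best_start, best_len = run_start, k - run_start
                run_start = None
        if best_len >= 3:  # span > one grid step
            bistable = True
            interval = (
                float(i_grid[best_start]),
                float(i_grid[best_start + best_len - 1]),
            )

    return BifurcationDiagram(
        i_grid=i_grid,
        up_extrema=up_extrema,
        down_extrema=down_extrema,
        onset_current=onset,
        offset_current=offset,
        bistable=bistable,
        bistable_interval=interval,
        amplitude_threshold_mv=amplitude_threshold_mv,
        failed_points=tuple(failed_points),
    )


def run_diagram(
    params: NeuronParams,
    i_grid,
    settle_ms: float = DEFAULT_SETTLE_MS,
    window_ms: float = DEFAULT_WINDOW_MS,
    dt_ms: float = 0.02,
    method: str = "rk4",
    amplitude_threshold_mv: float = AMPLITUDE_THRESHOLD_MV,
) -> BifurcationDiagram:
    """Up- and down-sweep one condition and classify the result."""
    up, f1 = sweep(params, i_grid, "up", settle_ms, window_ms, dt_ms, method)
    down, f2 = sweep(params, i_grid, "down", settle_ms, window_ms, dt_ms, method)
    return classify(up, down, i_grid, amplitude_threshold_mv, f1 + f2)


def bistable_width(diagram: BifurcationDiagram) -> float:
    if not diagram.bistable:
        return 0.0
    lo, hi = diagram.bistable_interval
    return hi - lo


def compare_conditions(diagrams: dict) -> dict:
    """Offset-current ordering and bistability report across conditions.

    Expects the four condition diagrams on identical grids.  Reports the
    per-condition offset currents and bistable-interval widths, which
    condition admits the largest offset (with ties within one grid step
    flagged rather than silently ordered), and whether the bistable width
    is non-increasing across WT37 -> WT40 -> AV37 -> AV40.
    """
    required = ("WT37", "WT40", "AV37", "AV40")
    missing = [lab for lab in required if lab not in diagrams]
    if missing:
        raise ValueError(f"missing condition diagram(s): {missing}")
    grids = [np.asarray(diagrams[lab].i_grid) for lab in required]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("diagrams must share one current grid")
    step = float(np.diff(grids[0]).max())

    offsets = {lab: diagrams[lab].offset_current for lab in required}
    widths = {lab: bistable_width(diagrams[lab]) for lab in required}
    finite = {lab: off for lab, off in offsets.items() if off is not None}
    max_lab = max(finite, key=finite.get) if finite else None
    ties = [
        lab for lab in finite
        if lab != max_lab and abs(finite[lab] - finite[max_lab]) <= step
    ]

    def _gt(a, b):
        return (
            offsets[a] is not None
            and (offsets[b] is None or offsets[a] > offsets[b])
        )

    w = [widths[lab] for lab in required]
    return {
        "offset_currents": offsets,
        "bistable": {lab: diagrams[lab].bistable for lab in required},
        "bistable_widths": widths,
        "max_offset_condition": max_lab,
        "max_offset_ties": ties,
        "av40_is_max": max_lab == "AV40" and not ties,
        "av37_gt_wt37": _gt("AV37", "WT37"),
        "av40_gt_wt40": _gt("AV40", "WT40"),
        "widths_non_increasing": all(w[i] >= w[i + 1] for i in range(3)),
    }
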