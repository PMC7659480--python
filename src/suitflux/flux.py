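"""From oxygen traces to per-state, corrected, cell-normalized fluxes.

The pipeline implemented here mirrors what an oxygraph operator does by hand:

1. differentiate the O2 concentration trace to a volume-specific flux
   (``j_total``, pmol O2/(s·mL), respiration positive = O2 removal),
   re-estimating the slope independently on each inter-event segment so the
   smoothing window never averages across a titration step;
2. subtract the calibrated linear-in-O2 instrumental background
   ``a + b·C(t)`` to get the sample flux ``j_sample``;
3. normalize by cell density to ``j_cell`` in pmol/(s·10^6 cells);
4. segment the run into respiratory states from the titration events;
5. place a steady-state mark (the minimum-variance window after a settling
   exclusion) in each state, take the maximum across CCCP titration steps as
   the ETS plateau, and subtract the residual (ROX) flux from every state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .protocol import (
    ChamberConfig,
    Diagnostic,
    OxygenTrace,
    RunRecord,
    State,
    validate_run,
)

__all__ = [
    "FluxSeries",
    "SteadyStateMark",
    "StateFluxTable",
    "derive_flux",
    "subtract_background",
    "normalize_per_cells",
    "segment_states",
    "mark_steady_state",
    "state_fluxes",
]

_UM_PER_S_TO_PMOL_PER_S_ML = 1000.0  # 1 µM/s over 1 mL = 1000 pmol/(s·mL)
_MIN_WINDOW_SAMPLES = 5


@dataclass
class FluxSeries:
    """Oxygen flux on the trace's time grid.

    ``j_total`` is the volume-specific chamber flux; ``j_sample`` the same
    after background subtraction; ``j_cell`` the per-million-cells flux.
    The latter two are filled by :func:`subtract_background` and
    :func:`normalize_per_cells`.
    """

    time: np.ndarray
    j_total: np.ndarray
    j_sample: np.ndarray | None = None
    j_cell: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("j_total", "j_sample", "j_cell"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} does not match the time grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)


@dataclass(frozen=True)
class SteadyStateMark:
    """A plateau mark: the window used to read one state's flux."""

    state: State
    t_start: float
    t_end: float
    mean_flux: float  # pmol/(s·10^6 cells)
    sd_flux: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("mark window must have t_start < t_end")
        if self.n_points < _MIN_WINDOW_SAMPLES:
            raise ValueError(f"mark needs >= {_MIN_WINDOW_SAMPLES} points")


@dataclass
class StateFluxTable:
    """Per-run, per-state oxygen fluxes: the pipeline's central intermediate.

    ``raw`` holds background-corrected, cell-normalized plateau fluxes;
    ``corrected`` the same after subtracting the residual oxygen consumption
    (``rox_value``), so ``corrected[ROX] == 0`` exactly.
    """

    sample_id: str
    group: str
    protocol_name: str
    raw: dict[State, float]
    corrected: dict[State, float]
    sd: dict[State, float]
    windows: dict[State, tuple[float, float]]
    rox_value: float
    warnings: list[Diagnostic] = field(default_factory=list)

    def to_frame(self):
        """Long-format table: one row per state."""
        import pandas as pd

        rows = []
        for state in self.raw:
            w = self.windows[state]
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "group": self.group,
                    "state": state.value,
                    "raw_flux": self.raw[state],
                    "rox_corrected_flux": self.corrected[state],
                    "t_start": w[0],
                    "t_end": w[1],
                    "sd_flux": self.sd[state],
                }
            )
        return pd.DataFrame(rows)


def _window_samples(time: np.ndarray, window_s: float) -> int:
    dt = float(np.median(np.diff(time)))
    return int(round(window_s / dt)) + 1


def _segment_bounds(time: np.ndarray, event_times) -> list[tuple[int, int]]:
    """Half-open sample-index ranges delimited by event times."""
    cuts = [0]
    for t in sorted(event_times or []):
        idx = int(np.searchsorted(time, t))
        if 0 < idx < time.size and idx != cuts[-1]:
            cuts.append(idx)
    cuts.append(time.size)
    return [(a, b) for a, b in zip(cuts, cuts[1:]) if b - a > 0]


def _sliding_slopes(t: np.ndarray, y: np.ndarray, n_w: int) -> np.ndarray:
    """Slope of a local least-squares line at every sample.

    Windows are ``n_w`` samples wide, centered where possible and one-sided
    (full width, shifted inward) at the segment ends.  Vectorized with
    prefix sums; ``t`` is re-centered to keep the normal equations well
    conditioned.
    """
    n = t.size
    if n_w > n:
        n_w = n
    t = t - t[0]
    c1 = np.concatenate(([0.0], np.cumsum(t)))
    c2 = np.concatenate(([0.0], np.cumsum(t * t)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cty = np.concatenate(([0.0], np.cumsum(t * y)))

    centered = np.arange(n) - n_w // 2
    starts = np.clip(centered, 0, n - n_w)
    ends = starts + n_w
    s1 = c1[ends] - c1[starts]
    s2 = c2[ends] - c2[starts]
    sy = cy[ends] - cy[starts]
    sty = cty[ends] - cty[starts]
    denom = n_w * s2 - s1 * s1
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n_w * sty - s1 * sy) / denom
    slope = np.where(denom > 0, slope, 0.0)
    # At the segment ends the window is one-sided, and a local line read
    # away from its centroid is biased on curved traces; refit those few
    # points with a local quadratic and take its derivative at t_i.
    for i in np.flatnonzero(starts != centered):
        a, b = int(starts[i]), int(ends[i])
        if b - a >= 3:
            coef = np.polynomial.polynomial.polyfit(t[a:b], y[a:b], 2)
            slope[i] = coef[1] + 2.0 * coef[2] * t[i]
    return slope


def derive_flux(
    trace: OxygenTrace,
    window_s: float = 20.0,
    method: str = "sliding-regression",
    event_times=None,
) -> FluxSeries:
    """Differentiate a concentration trace into volume-specific flux.

    ``j_total(t) = -dC/dt × 1000`` (µM/s → pmol/(s·mL)); positive flux is
    O2 removal from the chamber.  The derivative is estimated independently
    on each inter-event segment (``event_times``) so smoothing never crosses
    a titration step; within a segment a sliding local linear regression
    (default) or a Savitzky–Golay first derivative is used.
    """
    if method not in ("sliding-regression", "savitzky-golay"):
        raise ValueError(f"unknown derivative method {method!r}")
    time, conc = trace.time, trace.o2
    n_w = _window_samples(time, window_s)
    if n_w < _MIN_WINDOW_SAMPLES:
        raise ValueError("derivative window must span at least 5 samples")

    dcdt = np.empty_like(conc)
    for a, b in _segment_bounds(time, event_times):
        t_seg, y_seg = time[a:b], conc[a:b]
        if b - a < 2:
            dcdt[a:b] = 0.0
            continue
        if method == "sliding-regression":
            dcdt[a:b] = _sliding_slopes(t_seg, y_seg, n_w)
        else:
            w = min(n_w, b - a)
            if w % 2 == 0:
                w -= 1
            if w < 3:
                dcdt[a:b] = np.gradient(y_seg, t_seg)
            else:
                dt = float(np.median(np.diff(t_seg)))
                dcdt[a:b] = savgol_filter(
                    y_seg, window_length=w, polyorder=2, deriv=1, delta=dt,
                    mode="interp",
                )
    return FluxSeries(time=time, j_total=-dcdt * _UM_PER_S_TO_PMOL_PER_S_ML)


def subtract_background(
    flux: FluxSeries, trace: OxygenTrace, chamber: ChamberConfig
) -> FluxSeries:
    """Remove the calibrated instrumental background ``a + b·C(t)``."""
    if flux.time.shape != trace.time.shape or not np.allclose(
        flux.time, trace.time
    ):
        raise ValueError("flux and trace are on different time grids")
    bg = chamber.background_a + chamber.background_b * trace.o2
    return FluxSeries(
        time=flux.time, j_total=flux.j_total, j_sample=flux.j_total - bg
    )


def normalize_per_cells(flux: FluxSeries, chamber: ChamberConfig) -> FluxSeries:
    """Convert to per-million-cells flux: ``j_cell = j_sample × V / N``."""
    if flux.j_sample is None:
        raise ValueError("background-subtracted flux (j_sample) required first")
    if not chamber.cell_count > 0:
        raise ValueError("cell_count must be > 0")
    j_cell = flux.j_sample * chamber.volume / chamber.cell_count
    return FluxSeries(
        time=flux.time,
        j_total=flux.j_total,
        j_sample=flux.j_sample,
        j_cell=j_cell,
    )


def segment_states(run: RunRecord) -> list[tuple[State, float, float]]:
    """Map the run's titration events onto respiratory-state time spans.

    ROUTINE spans acquisition start to the first event; each later state
    spans its triggering event to the next event (trace end for the last).
    Consecutive spans of the same state (glutamate under SUIT_MAIN, the
    rotenone/ADP null under SUIT_CII) are merged, except CCCP steps: each
    uncoupler step stays a separate ETS candidate sub-segment.
    """
    t0, t1 = run.trace.span
    if not run.events:
        return [(State.ROUTINE, t0, t1)]
    errors = [d for d in validate_run(run) if d.severity == "error"]
    if errors:
        raise ValueError(
            "run does not satisfy its protocol: "
            + "; ".join(d.message for d in errors)
        )
    events = sorted(run.events, key=lambda e: e.time)
    state_by_trigger: dict = {}
    for tr in run.protocol.transitions:
        state_by_trigger[tr.trigger] = tr.state

    spans: list[tuple[State, float, float]] = [
        (State.ROUTINE, t0, events[0].time)
    ]
    for k, ev in enumerate(events):
        end = events[k + 1].time if k + 1 < len(events) else t1
        state = state_by_trigger[ev.reagent]
        if (
            spans
            and spans[-1][0] is state
            and state is not State.ETS  # keep CCCP candidates separate
        ):
            spans[-1] = (state, spans[-1][1], end)
        else:
            spans.append((state, ev.time, end))
    return [(s, a, b) for s, a, b in spans if b > a]


def _latest_subsegment(
    segment: tuple[State, float, float], event_times
) -> tuple[State, float, float]:
    """Shrink a merged state span to its latest event-delimited piece."""
    state, t_start, t_end = segment
    interior = [t for t in event_times if t_start < t < t_end]
    if interior:
        t_start = max(interior)
    return (state, t_start, t_end)


def mark_steady_state(
    flux: FluxSeries,
    segment: tuple[State, float, float],
    settle_s: float = 60.0,
    window_s: float | None = None,
) -> SteadyStateMark:
    """Place a plateau mark inside one state segment.

    After excluding ``settle_s`` seconds of mixing/response transient, the
    window of length ``window_s`` with the smallest flux standard deviation
    is chosen; on ties the latest such window wins (plateaus drift toward
    steady state, so later is safer).  ``window_s=None`` (the default) uses
    the entire post-settle plateau as the mark: with white sensor noise the
    flux-estimate variance falls with the cube of the marked span, so
    discarding plateau data costs precision for no robustness gain.
    """
    if flux.j_cell is None:
        raise ValueError("cell-normalized flux (j_cell) required for marking")
    state, t_start, t_end = segment
    lo = t_start + settle_s
    if window_s is None:
        window_s = t_end - lo
    if t_end - lo < window_s:
        raise ValueError(
            f"segment {state.value} [{t_start}, {t_end}] s too short for "
            f"settle_s={settle_s} + window_s={window_s}; reduce the windows"
        )
    sel = (flux.time >= lo) & (flux.time < t_end)
    t = flux.time[sel]
    y = flux.j_cell[sel]
    n_w = min(_window_samples(t, window_s), t.size) if t.size else 0
    if t.size < _MIN_WINDOW_SAMPLES or n_w < _MIN_WINDOW_SAMPLES:
        raise ValueError(
            f"segment {state.value} has only {t.size} usable samples; "
            f"reduce settle_s or window_s"
        )
    win = np.lib.stride_tricks.sliding_window_view(y, n_w)
    sd = win.std(axis=1, ddof=1)
    best = int(np.flatnonzero(sd <= sd.min()).max())  # latest minimal-sd window
    return SteadyStateMark(
        state=state,
        t_start=float(t[best]),
        t_end=float(t[best + n_w - 1]),
        mean_flux=float(win[best].mean()),
        sd_flux=float(sd[best]),
        n_points=n_w,
    )


def state_fluxes(
    run: RunRecord,
    settle_s: float = 60.0,
    window_s: float | None = None,
    derivative_method: str = "sliding-regression",
    derivative_window_s: float = 20.0,
) -> StateFluxTable:
    """Full trace→table pipeline for one run.

    Composes derive → background-subtract → cell-normalize → segment → mark.
    States that a later reagent re-enters (glutamate under the main
    protocol, ADP after rotenone in the CII protocol) are marked on their
    latest sub-segment, so the mark never spans an intervening addition's
    mixing transient.  The ETS flux is the maximum plateau across CCCP
    titration sub-segments (over-titration depresses respiration, so the
    optimal step is the maximum, not the last).  Every state is then
    corrected by subtracting the residual (ROX) flux; negative corrected
    fluxes are kept as-is with a warning, never clamped, because clamping
    would bias the ratios built on top of them.
    """
    event_times = [e.time for e in run.events]
    fx = derive_flux(
        run.trace,
        window_s=derivative_window_s,
        method=derivative_method,
        event_times=event_times,
    )
    fx = subtract_background(fx, run.trace, run.chamber)
    fx = normalize_per_cells(fx, run.chamber)
    segments = segment_states(run)

    warnings: list[Diagnostic] = list(run.warnings)
    marks: dict[State, SteadyStateMark] = {}
    ets_candidates: list[SteadyStateMark] = []
    # Within half a derivative window of a segment's end the slope estimate
    # is one-sided (no samples beyond the next titration), which inflates
    # its variance; keep marks on interior, fully-windowed estimates only.
    edge_s = derivative_window_s / 2.0
    for seg in segments:
        seg = _latest_subsegment(seg, event_times)
        seg = (seg[0], seg[1], seg[2] - edge_s)
        mark = mark_steady_state(fx, seg, settle_s=settle_s, window_s=window_s)
        if seg[0] is State.ETS:
            ets_candidates.append(mark)
        else:
            marks[seg[0]] = mark
    if ets_candidates:
        marks[State.ETS] = max(ets_candidates, key=lambda m: m.mean_flux)

    if State.ROX not in marks:
        raise ValueError("no ROX state in run; cannot apply residual correction")
    rox = marks[State.ROX].mean_flux

    raw = {s: m.mean_flux for s, m in marks.items()}
    corrected = {s: v - rox for s, v in raw.items()}
    corrected[State.ROX] = 0.0
    for s, v in corrected.items():
        if v < 0 and s is not State.ROX:
            warnings.append(
                Diagnostic(
                    "warning",
                    f"ROX-corrected flux for {s.value} is negative "
                    f"({v:.3g}); reported unclamped",
                )
            )
    return StateFluxTable(
        sample_id=run.trace.sample_id,
        group=run.group,
        protocol_name=run.protocol.name,
        raw=raw,
        corrected=corrected,
        sd={s: m.sd_flux for s, m in marks.items()},
        windows={s: (m.t_start, m.t_end) for s, m in marks.items()},
        rox_value=rox,
        warnings=warnings,
    )
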