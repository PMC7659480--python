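"""CSV and JSON interchange for traces, events, tables and runs.

All artifacts are tidy UTF-8 CSV with '.' decimal separator:

- trace CSV: ``time_s,o2_um`` (+ optional ``chamber_id,sample_id``);
- event CSV: ``time_s,reagent,dose,units``;
- state-flux CSV: one row per run x state;
- metrics CSV: long format ``sample_id,group,metric,state,value``;
- comparison report CSV: one row per contrast.

Only this documented dialect is read; vendor instrument exports must be
reshaped to it externally.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .flux import StateFluxTable
from .group_stats import GroupComparison
from .protocol import (
    ChamberConfig,
    OxygenTrace,
    ProtocolDefinition,
    Reagent,
    RunRecord,
    State,
    TitrationEvent,
    Transition,
    builtin_protocol,
)

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_events_csv",
    "write_events_csv",
    "state_flux_frame",
    "write_state_flux_csv",
    "write_metrics_csv",
    "read_metrics_csv",
    "comparison_frame",
    "write_comparison_csv",
    "format_comparison_table",
    "run_to_dict",
    "run_from_dict",
]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"found {', '.join(df.columns)}"
        )


def read_trace_csv(path) -> OxygenTrace:
    """Read an oxygen trace (``time_s,o2_um``) from CSV."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "o2_um"], path)
    time = df["time_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(time) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: non-monotonic time at data line {int(bad[0]) + 2}"
        )
    kwargs = {}
    if "chamber_id" in df.columns:
        kwargs["chamber_id"] = str(df["chamber_id"].iloc[0])
    if "sample_id" in df.columns:
        kwargs["sample_id"] = str(df["sample_id"].iloc[0])
    return OxygenTrace(time=time, o2=df["o2_um"].to_numpy(float), **kwargs)


def write_trace_csv(trace: OxygenTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "o2_um": trace.o2,
            "chamber_id": trace.chamber_id,
            "sample_id": trace.sample_id,
        }
    )
    df.to_csv(path, index=False)


def read_events_csv(path) -> list[TitrationEvent]:
    """Read a titration-event log (``time_s,reagent,dose,units``) from CSV."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "reagent"], path)
    events = []
    for i, row in df.iterrows():
        try:
            reagent = Reagent(str(row["reagent"]).strip())
        except ValueError:
            raise ValueError(
                f"{path}: unknown reagent {row['reagent']!r} at data line {i + 2}"
            ) from None
        dose = row.get("dose")
        dose = float(dose) if dose is not None and pd.notna(dose) else None
        units = row.get("units")
        units = str(units) if units is not None and pd.notna(units) else None
        events.append(
            TitrationEvent(float(row["time_s"]), reagent, dose=dose, units=units)
        )
    return events


def write_events_csv(events, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "reagent": [e.reagent.value for e in events],
            "dose": [e.dose for e in events],
            "units": [e.units for e in events],
        }
    )
    df.to_csv(path, index=False)


def state_flux_frame(tables) -> pd.DataFrame:
    """Stack StateFluxTables into one long-format DataFrame."""
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


def write_state_flux_csv(tables, path) -> None:
    state_flux_frame(tables).to_csv(path, index=False)


def write_metrics_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _require_columns(df, ["sample_id", "group", "metric", "state", "value"], path)
    df["state"] = df["state"].fillna("").astype(str)
    return df


def comparison_frame(comparisons) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "metric": c.metric,
                "state": c.state,
                "mean_control": c.mean_control,
                "sd_control": c.sd_control,
                "n_control": c.n_control,
                "mean_treated": c.mean_treated,
                "sd_treated": c.sd_treated,
                "n_treated": c.n_treated,
                "percent_change": c.percent_change,
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
                "significance": c.significance,
            }
        )
    return pd.DataFrame(rows)


def write_comparison_csv(comparisons, path) -> None:
    comparison_frame(comparisons).to_csv(path, index=False)


def format_comparison_table(comparisons) -> str:
    """Human-readable fixed-width contrast panel."""
    header = (
        f"{'metric':<22}{'state':<11}{'control':>24}{'treated':>24}"
        f"{'change':>10}{'p':>11}  sig"
    )
    lines = [header, "-" * len(header)]
    for c in comparisons:
        sc = f"{c.sd_control:.3g}" if c.sd_control is not None else "-"
        st = f"{c.sd_treated:.3g}" if c.sd_treated is not None else "-"
        change = (
            f"{c.percent_change:+.1f}%"
            if c.percent_change == c.percent_change  # not NaN
            else "n/a"
        )
        lines.append(
            f"{c.metric:<22}{c.state:<11}"
            f"{f'{c.mean_control:.3g} ± {sc} (n={c.n_control})':>24}"
            f"{f'{c.mean_treated:.3g} ± {st} (n={c.n_treated})':>24}"
            f"{change:>10}"
            f"{c.p_value:>11.4g}  {c.significance}"
        )
    return "\n".join(lines)


# --- run (de)serialization ---------------------------------------------------


def run_to_dict(run: RunRecord) -> dict:
    """JSON-compatible dict reproducing the run bit-identically on parse."""
    p = run.protocol
    return {
        "trace": {
            "time": run.trace.time.tolist(),
            "o2": run.trace.o2.tolist(),
            "chamber_id": run.trace.chamber_id,
            "sample_id": run.trace.sample_id,
            "temperature": run.trace.temperature,
        },
        "events": [
            {"time": e.time, "reagent": e.reagent.value, "dose": e.dose,
             "units": e.units}
            for e in run.events
        ],
        "chamber": {
            "cell_count": run.chamber.cell_count,
            "volume": run.chamber.volume,
            "stirring": run.chamber.stirring,
            "background_a": run.chamber.background_a,
            "background_b": run.chamber.background_b,
        },
        "protocol": {
            "name": p.name,
            "transitions": [
                {
                    "trigger": t.trigger.value,
                    "state": t.state.value,
                    "repeatable": t.repeatable,
                    "optional": t.optional,
                }
                for t in p.transitions
            ],
            "ets_rule": p.ets_rule,
            "reference_state": p.reference_state.value,
            "paired_reference": p.paired_reference,
            "doses": {
                (k.value if isinstance(k, Reagent) else str(k)): v
                for k, v in p.doses.items()
            },
        },
        "group": run.group,
    }


def run_from_dict(d: dict) -> RunRecord:
    tr = d["trace"]
    trace = OxygenTrace(
        time=np.asarray(tr["time"], dtype=float),
        o2=np.asarray(tr["o2"], dtype=float),
        chamber_id=tr["chamber_id"],
        sample_id=tr["sample_id"],
        temperature=tr["temperature"],
    )
    events = [
        TitrationEvent(e["time"], Reagent(e["reagent"]), e["dose"], e["units"])
        for e in d["events"]
    ]
    chamber = ChamberConfig(**d["chamber"])
    pr = d["protocol"]
    protocol = ProtocolDefinition(
        name=pr["name"],
        transitions=tuple(
            Transition(
                Reagent(t["trigger"]),
                State(t["state"]),
                repeatable=t["repeatable"],
                optional=t["optional"],
            )
            for t in pr["transitions"]
        ),
        ets_rule=pr["ets_rule"],
        reference_state=State(pr["reference_state"]),
        paired_reference=pr["paired_reference"],
        doses={Reagent(k): v for k, v in pr["doses"].items()},
    )
    return RunRecord(
        trace=trace, events=events, chamber=chamber, protocol=protocol,
        group=d["group"],
    )


def save_run_json(run: RunRecord, path) -> None:
    Path(path).write_text(json.dumps(run_to_dict(run)))


def load_run_json(path) -> RunRecord:
    return run_from_dict(json.loads(Path(path).read_text()))
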