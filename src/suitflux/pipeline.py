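"""High-level orchestration: runs → tables → metrics → group contrasts."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

from .flux import StateFluxTable, state_fluxes
from .group_stats import GroupComparison, compare
from .metrics import RR_OXPHOS_MINUS_ROUTINE, compute_metrics, scf_cii
from .protocol import RunRecord

__all__ = [
    "AnalysisConfig",
    "analyze_runs",
    "scf_frame",
    "compare_metrics",
]


@dataclass
class AnalysisConfig:
    """Tunable analysis settings shared by the CLI and the library."""

    protocol: str = "SUIT_MAIN"
    derivative_method: str = "sliding-regression"  # or "savitzky-golay"
    derivative_window_s: float = 20.0
    settle_s: float = 60.0
    window_s: float | None = None  # None = mark the full post-settle plateau
    ttest_variant: str = "student"  # or "welch"
    rr_definition: str = RR_OXPHOS_MINUS_ROUTINE
    out_dir: str = "."
    verbosity: int = 1

    def __post_init__(self) -> None:
        for name in ("derivative_window_s", "settle_s", "window_s"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def analyze_runs(
    runs: list[RunRecord], config: AnalysisConfig | None = None
) -> tuple[list[StateFluxTable], pd.DataFrame]:
    """State-flux tables and a stacked long-format metrics frame."""
    config = config or AnalysisConfig()
    tables = [
        state_fluxes(
            run,
            settle_s=config.settle_s,
            window_s=config.window_s,
            derivative_method=config.derivative_method,
            derivative_window_s=config.derivative_window_s,
        )
        for run in runs
    ]
    frames = [compute_metrics(t, rr_definition=config.rr_definition) for t in tables]
    return tables, pd.concat(frames, ignore_index=True)


def scf_frame(
    cii_tables: list[StateFluxTable], reference_tables: list[StateFluxTable]
) -> pd.DataFrame:
    """Substrate control factors for CII runs paired by sample_id."""
    refs = {t.sample_id: t for t in reference_tables}
    rows = []
    for t in cii_tables:
        if t.sample_id not in refs:
            raise ValueError(f"no paired reference run for sample {t.sample_id!r}")
        rows.append(
            {
                "sample_id": t.sample_id,
                "group": t.group,
                "metric": "scf_cii",
                "state": "",
                "value": scf_cii(t, refs[t.sample_id]),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "group", "metric", "state", "value"])


def compare_metrics(
    metrics: pd.DataFrame,
    control_group: str,
    treated_group: str,
    variant: str = "student",
    min_n: int = 2,
) -> tuple[list[GroupComparison], list[str]]:
    """Contrast every (metric, state) family between two groups.

    Runs missing a value for some family are excluded from that family
    with a logged message (returned alongside), decrementing its n; a
    family is skipped entirely if either group drops below ``min_n``.
    """
    logs: list[str] = []
    comparisons: list[GroupComparison] = []
    metrics = metrics.copy()
    metrics["state"] = metrics["state"].fillna("")
    families = (
        metrics[["metric", "state"]].drop_duplicates().itertuples(index=False)
    )
    for metric, state in families:
        sub = metrics[(metrics["metric"] == metric) & (metrics["state"] == state)]
        vals = {}
        for grp in (control_group, treated_group):
            g = sub[sub["group"] == grp]["value"].dropna()
            expected = metrics[metrics["group"] == grp]["sample_id"].nunique()
            if len(g) < expected:
                logs.append(
                    f"{metric}/{state or '-'}: {expected - len(g)} {grp} run(s) "
                    f"missing a value; n decremented to {len(g)}"
                )
            vals[grp] = g.to_numpy()
        if any(len(v) < min_n for v in vals.values()):
            logs.append(
                f"{metric}/{state or '-'}: fewer than {min_n} runs per group; skipped"
            )
            continue
        comparisons.append(
            compare(
                vals[control_group],
                vals[treated_group],
                variant=variant,
                metric=metric,
                state=state,
            )
        )
    return comparisons, logs
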