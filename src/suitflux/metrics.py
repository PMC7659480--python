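"""Derived respiratory ratios from a per-run state-flux table.

All ratios are built on ROX-corrected fluxes.  The reference for flux
control ratios (FCRs) is the maximal uncoupled ETS capacity; net (ATP-
coupled) ratios additionally subtract LEAK; coupling efficiency expresses
the LEAK-corrected flux as a fraction of that state's own total; the
respiratory reserve is the spare phosphorylating capacity above ROUTINE
demand; the complex II substrate control factor (SCF) normalizes the
CII-driven OXPHOS of a rotenone-first run by the convergent CI+CII OXPHOS
of a paired reference run.
"""

from __future__ import annotations

import warnings as _warnings

import pandas as pd

from .flux import StateFluxTable
from .protocol import State

__all__ = [
    "fcr",
    "net_fcr",
    "coupling_efficiency",
    "respiratory_reserve",
    "scf_cii",
    "cii_ets_fcr",
    "percent_change",
    "compute_metrics",
    "RR_OXPHOS_MINUS_ROUTINE",
    "RR_ETS_MINUS_ROUTINE",
]

RR_OXPHOS_MINUS_ROUTINE = "oxphos_minus_routine"
RR_ETS_MINUS_ROUTINE = "ets_minus_routine"

# States in which a coupling efficiency is meaningful (phosphorylating or
# uncoupled respiration on top of LEAK).
COUPLING_STATES = (State.ROUTINE, State.OXPHOS_CI, State.OXPHOS, State.ETS)


def _corrected(table: StateFluxTable, state: State) -> float:
    try:
        return table.corrected[State(state)]
    except KeyError:
        raise ValueError(f"state {State(state).value} absent from table") from None


def _reference(table: StateFluxTable) -> float:
    ref = _corrected(table, State.ETS)
    if ref == 0:
        raise ZeroDivisionError("degenerate reference: ROX-corrected ETS flux is 0")
    return ref


def fcr(table: StateFluxTable, state: State) -> float:
    """Flux control ratio: corrected state flux over corrected ETS flux."""
    return _corrected(table, state) / _reference(table)


def net_fcr(table: StateFluxTable, state: State) -> float:
    """ATP-coupled (net) FCR: LEAK-corrected state flux over ETS flux.

    Identity: ``net_fcr(s) == fcr(s) - fcr(LEAK)``.
    """
    leak = _corrected(table, State.LEAK)
    return (_corrected(table, state) - leak) / _reference(table)


def coupling_efficiency(table: StateFluxTable, state: State) -> float:
    """Coupled fraction of a state's respiration: ``1 - LEAK/state``.

    Stored as a fraction; multiply by 100 to render as percent.
    """
    total = _corrected(table, state)
    if total == 0:
        raise ZeroDivisionError(
            f"coupling efficiency undefined: corrected {State(state).value} flux is 0"
        )
    return (total - _corrected(table, State.LEAK)) / total


def respiratory_reserve(
    table: StateFluxTable, definition: str = RR_OXPHOS_MINUS_ROUTINE
) -> float:
    """Spare phosphorylating capacity above ROUTINE demand, in FCR units.

    Default: ``(OXPHOS - ROUTINE) / ETS`` — the extra ATP-producing flux
    available when demand rises.  The alternative reading
    ``(ETS - ROUTINE) / ETS`` (spare capacity up to the uncoupled maximum)
    is available via ``definition="ets_minus_routine"``.  LEAK cancels out
    of either definition.
    """
    if definition == RR_OXPHOS_MINUS_ROUTINE:
        upper = _corrected(table, State.OXPHOS)
    elif definition == RR_ETS_MINUS_ROUTINE:
        upper = _corrected(table, State.ETS)
    else:
        raise ValueError(f"unknown respiratory-reserve definition {definition!r}")
    return (upper - _corrected(table, State.ROUTINE)) / _reference(table)


def cii_ets_fcr(table: StateFluxTable) -> float:
    """FCR of the ETS sustained by complex II (after rotenone)."""
    return _corrected(table, State.ETS_CII) / _reference(table)


def scf_cii(
    cii_table: StateFluxTable, reference_table: StateFluxTable
) -> float:
    """Complex II substrate control factor.

    The CII-driven OXPHOS flux of a rotenone-first run (residual-corrected
    against its post-malonate baseline) divided by the convergent CI+CII
    OXPHOS flux of the paired no-rotenone reference run.  Values outside
    [0, 1] are reported with a warning, never clamped.
    """
    if (
        cii_table.sample_id
        and reference_table.sample_id
        and cii_table.sample_id != reference_table.sample_id
    ):
        raise ValueError(
            f"unpaired runs: {cii_table.sample_id!r} vs "
            f"{reference_table.sample_id!r}"
        )
    num = _corrected(cii_table, State.OXPHOS_CII)
    den = _corrected(reference_table, State.OXPHOS)
    if den == 0:
        raise ZeroDivisionError("reference OXPHOS flux is 0")
    value = num / den
    if not 0.0 <= value <= 1.0:
        _warnings.warn(
            f"SCF {value:.3g} outside [0, 1]; CII-linked flux should not "
            "exceed the convergent CI+CII flux",
            stacklevel=2,
        )
    return value


def percent_change(
    control_value: float, treated_value: float, ndigits: int = 1
) -> float:
    """Signed percent change of treated relative to control.

    ``(treated - control) / control × 100``, rounded to ``ndigits``
    decimals (one by default, matching how such contrasts are reported).
    """
    if control_value == 0:
        raise ZeroDivisionError("percent change undefined for control value 0")
    return round((treated_value - control_value) / control_value * 100.0, ndigits)


def compute_metrics(
    table: StateFluxTable, rr_definition: str = RR_OXPHOS_MINUS_ROUTINE
) -> pd.DataFrame:
    """All per-run metrics available from one table, long format.

    Columns: ``sample_id, group, metric, state, value``.  Emits FCR and net
    FCR for every non-ROX state present, coupling efficiencies where
    meaningful, the respiratory reserve and the CII-ETS FCR when their
    states are present.  The SCF needs a paired reference run and is not
    emitted here; see :func:`scf_cii`.
    """
    rows = []

    def add(metric: str, state: State | None, value: float) -> None:
        rows.append(
            {
                "sample_id": table.sample_id,
                "group": table.group,
                "metric": metric,
                "state": state.value if state is not None else "",
                "value": value,
            }
        )

    has_ets = State.ETS in table.corrected
    has_leak = State.LEAK in table.corrected
    if has_ets and table.corrected[State.ETS] != 0:
        for state in table.corrected:
            if state is State.ROX:
                continue
            add("fcr", state, fcr(table, state))
            if has_leak:
                add("net_fcr", state, net_fcr(table, state))
        if has_leak:
            for state in COUPLING_STATES:
                if state in table.corrected and table.corrected[state] != 0:
                    add("coupling_efficiency", state, coupling_efficiency(table, state))
        if State.ROUTINE in table.corrected and State.OXPHOS in table.corrected:
            add(
                "respiratory_reserve",
                None,
                respiratory_reserve(table, rr_definition),
            )
        if State.ETS_CII in table.corrected:
            add("cii_ets_fcr", None, cii_ets_fcr(table))
    for state, value in table.corrected.items():
        add("flux", state, value)
    return pd.DataFrame(rows, columns=["sample_id", "group", "metric", "state", "value"])
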