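"""Domain types for oxygraph runs and SUIT titration protocols.

A SUIT (substrate–uncoupler–inhibitor titration) experiment walks one cell
sample through a sequence of respiratory states by timed reagent additions
into a closed, stirred oxygraph chamber.  This module defines the vocabulary
(reagents, states), the raw-data containers (trace, events, chamber) and the
protocol definitions that map an event sequence onto respiratory states,
including the two builtin protocols used throughout the package:

``SUIT_MAIN``
    intact-cell ROUTINE → digitonin permeabilization (pyruvate+malate
    pre-added) → LEAK → glutamate (still LEAK) → ADP → CI-supported OXPHOS →
    succinate → convergent CI+CII OXPHOS → stepwise CCCP titration → maximal
    uncoupled ETS → rotenone → CII-supported ETS → antimycin A → ROX.

``SUIT_CII``
    rotenone-first complex II protocol: LEAK → rotenone (complex I blocked,
    flux collapses) → ADP (no response) → succinate → CII-driven OXPHOS →
    malonate (CII blocked, baseline that plays the ROX role).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Reagent",
    "State",
    "Diagnostic",
    "OxygenTrace",
    "TitrationEvent",
    "ChamberConfig",
    "Transition",
    "ProtocolDefinition",
    "RunRecord",
    "builtin_protocol",
    "validate_run",
]


class Reagent(str, enum.Enum):
    """Closed vocabulary of titration reagents.

    PM is a single combined label: pyruvate and malate are co-added to the
    chamber before digitonin in both builtin protocols, so they never act as
    separate state triggers.
    """

    PM = "PM"      # pyruvate + malate (CI substrates, pre-added)
    DIG = "DIG"    # digitonin (plasma-membrane permeabilization)
    G = "G"        # glutamate (CI substrate)
    ADP = "ADP"    # saturating ADP (starts phosphorylation)
    S = "S"        # succinate (CII substrate)
    CCCP = "CCCP"  # protonophore uncoupler, titrated stepwise
    ROT = "ROT"    # rotenone (complex I inhibitor)
    AMA = "AMA"    # antimycin A (complex III inhibitor)
    MAL = "MAL"    # malonate / malonic acid (complex II inhibitor)


class State(str, enum.Enum):
    """Respiratory states a protocol can enter."""

    ROUTINE = "ROUTINE"
    LEAK = "LEAK"
    OXPHOS_CI = "OXPHOS_CI"
    OXPHOS = "OXPHOS"
    ETS = "ETS"
    ETS_CII = "ETS_CII"
    OXPHOS_CII = "OXPHOS_CII"
    ROX = "ROX"
    NULL = "NULL"


@dataclass(frozen=True)
class Diagnostic:
    """A validation finding: ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    message: str

    def __post_init__(self) -> None:
        if self.severity not in ("error", "warning"):
            raise ValueError(f"severity must be error/warning, got {self.severity!r}")


# O2 readings below this are physically impossible even as sensor noise.
_O2_HARD_FLOOR_UM = -5.0


@dataclass
class OxygenTrace:
    """Sampled chamber O2 concentration over time.

    Parameters
    ----------
    time : array of float
        Seconds from acquisition start; strictly increasing, >= 0.
    o2 : array of float
        O2 concentration in µM (= nmol/mL).  Small negative excursions from
        sensor noise are tolerated (flagged downstream); readings below
        -5 µM are rejected outright.
    chamber_id, sample_id : str
        Opaque labels.
    temperature : float
        °C, metadata only (default 37).
    """

    time: np.ndarray
    o2: np.ndarray
    chamber_id: str = "A"
    sample_id: str = ""
    temperature: float = 37.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.time.ndim != 1 or self.o2.ndim != 1:
            raise ValueError("time and o2 must be 1-D arrays")
        if self.time.size != self.o2.size:
            raise ValueError("time and o2 must have equal length")
        if self.time.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.time)) or not np.all(np.isfinite(self.o2)):
            raise ValueError("trace contains non-finite values")
        if self.time[0] < 0:
            raise ValueError("time must start at or after 0")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.o2 < _O2_HARD_FLOOR_UM):
            raise ValueError(
                f"o2 below {_O2_HARD_FLOOR_UM} µM is physically impossible"
            )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


@dataclass(frozen=True)
class TitrationEvent:
    """A timestamped reagent addition.

    ``dose`` and ``units`` are carried as metadata and never enter any
    computation.
    """

    time: float
    reagent: Reagent
    dose: float | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reagent", Reagent(self.reagent))


@dataclass(frozen=True)
class ChamberConfig:
    """Oxygraph chamber and sample metadata.

    ``background_a`` (pmol/(s·mL)) and ``background_b`` (pmol/(s·mL·µM))
    parameterize the linear-in-O2 instrumental/chemical background flux
    ``a + b·C``; they are assumed pre-calibrated.
    """

    cell_count: float  # millions of cells in the chamber
    volume: float = 2.0  # mL
    stirring: float = 750.0  # rpm, metadata
    background_a: float = 0.0
    background_b: float = 0.0

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError("chamber volume must be > 0")
        if not self.cell_count > 0:
            raise ValueError("cell_count must be > 0")


@dataclass(frozen=True)
class Transition:
    """One protocol step: the ``trigger`` reagent enters ``state``.

    ``repeatable`` marks uncoupler titration steps (CCCP may repeat);
    ``optional`` marks additions that may be absent without breaking the
    state sequence (glutamate re-enters LEAK, so a run without it still
    reaches every state).
    """

    trigger: Reagent
    state: State
    repeatable: bool = False
    optional: bool = False


@dataclass(frozen=True)
class ProtocolDefinition:
    """Ordered mapping from titration events to respiratory states.

    ``ets_rule`` names how the ETS plateau is located among CCCP titration
    steps (only ``"max_plateau"`` is defined: the step with the maximal
    steady flux, since over-titration depresses respiration).
    ``reference_state`` is the FCR denominator; ``paired_reference`` marks
    protocols (SUIT_CII) whose reference lives in a paired companion run.
    """

    name: str
    transitions: tuple[Transition, ...]
    ets_rule: str = "max_plateau"
    reference_state: State = State.ETS
    paired_reference: bool = False
    doses: dict = field(default_factory=dict)  # reagent -> human-readable dose

    def __post_init__(self) -> None:
        if not self.transitions:
            raise ValueError("protocol needs at least one transition")
        if self.ets_rule != "max_plateau":
            raise ValueError(f"unknown ets_rule {self.ets_rule!r}")
        State(self.reference_state)
        for t in self.transitions:
            Reagent(t.trigger)
            State(t.state)

    @property
    def states(self) -> list[State]:
        """States reachable by this protocol, ROUTINE first."""
        out = [State.ROUTINE]
        for t in self.transitions:
            if t.state not in out:
                out.append(t.state)
        return out


@dataclass
class RunRecord:
    """One oxygraph run: trace + events + chamber + protocol + group label."""

    trace: OxygenTrace
    events: list[TitrationEvent]
    chamber: ChamberConfig
    protocol: ProtocolDefinition
    group: str = "control"
    warnings: list[Diagnostic] = field(default_factory=list)


_SUIT_MAIN = ProtocolDefinition(
    name="SUIT_MAIN",
    transitions=(
        Transition(Reagent.DIG, State.LEAK),
        Transition(Reagent.G, State.LEAK, optional=True),
        Transition(Reagent.ADP, State.OXPHOS_CI),
        Transition(Reagent.S, State.OXPHOS),
        Transition(Reagent.CCCP, State.ETS, repeatable=True),
        Transition(Reagent.ROT, State.ETS_CII),
        Transition(Reagent.AMA, State.ROX),
    ),
    reference_state=State.ETS,
    doses={
        Reagent.PM: "5 mM pyruvate + 2 mM malate (pre-added)",
        Reagent.DIG: "4.07 µM digitonin",
        Reagent.G: "10 mM glutamate",
        Reagent.ADP: "2.5 mM ADP",
        Reagent.S: "10 mM succinate",
        Reagent.CCCP: "0.5 µM CCCP per step",
        Reagent.ROT: "2 µM rotenone",
        Reagent.AMA: "2.5 µM antimycin A",
    },
)

_SUIT_CII = ProtocolDefinition(
    name="SUIT_CII",
    transitions=(
        Transition(Reagent.DIG, State.LEAK),
        Transition(Reagent.ROT, State.NULL),
        Transition(Reagent.ADP, State.NULL),
        Transition(Reagent.S, State.OXPHOS_CII),
        Transition(Reagent.MAL, State.ROX),  # post-malonate baseline plays the ROX role
    ),
    reference_state=State.OXPHOS,
    paired_reference=True,
    doses={
        Reagent.PM: "5 mM pyruvate + 2 mM malate (pre-added)",
        Reagent.DIG: "4.07 µM digitonin",
        Reagent.ROT: "2 µM rotenone",
        Reagent.ADP: "2.5 mM ADP",
        Reagent.S: "10 mM succinate",
        Reagent.MAL: "5 mM malonic acid",
    },
)

_BUILTINS = {"SUIT_MAIN": _SUIT_MAIN, "SUIT_CII": _SUIT_CII}


def builtin_protocol(name: str) -> ProtocolDefinition:
    """Return a builtin protocol definition by name.

    Valid names: ``SUIT_MAIN`` (main respiratory-state protocol, FCR
    reference = maximal uncoupled ETS) and ``SUIT_CII`` (rotenone-first
    complex II protocol, referenced to the OXPHOS of a paired run).
    """
    try:
        proto = _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown protocol {name!r}; valid names are SUIT_MAIN, SUIT_CII"
        ) from None
    return replace(proto)  # defensive copy


def validate_run(run: RunRecord) -> list[Diagnostic]:
    """Check a run against its type invariants and its protocol.

    Returns a list of diagnostics; empty iff the run is fully conforming.
    Never raises: every defect becomes an error- or warning-severity
    :class:`Diagnostic` so callers can report all problems at once.
    """
    diags: list[Diagnostic] = []
    t0, t1 = run.trace.span

    if np.any(run.trace.o2 < 0):
        diags.append(
            Diagnostic(
                "warning",
                "negative O2 readings present (tolerated as sensor noise)",
            )
        )

    events = run.events
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        diags.append(Diagnostic("error", "events are not sorted by time"))
        events = sorted(events, key=lambda e: e.time)
    for e in events:
        if not (t0 <= e.time <= t1):
            diags.append(
                Diagnostic(
                    "error",
                    f"event {e.reagent.value} at t={e.time} s lies outside the "
                    f"trace span [{t0}, {t1}] s",
                )
            )

    from collections import Counter

    counts = Counter(e.reagent for e in events)
    for reagent, n in counts.items():
        if reagent is not Reagent.CCCP and n > 1:
            diags.append(
                Diagnostic(
                    "error",
                    f"reagent {reagent.value} appears {n} times; only CCCP may repeat",
                )
            )

    diags.extend(_check_order(events, run.protocol))
    return diags


def _check_order(
    events: list[TitrationEvent], protocol: ProtocolDefinition
) -> list[Diagnostic]:
    """Match the event sequence against the protocol's ordered transitions."""
    diags: list[Diagnostic] = []
    seq = [e.reagent for e in events]
    i = 0
    for tr in protocol.transitions:
        if tr.repeatable:
            n = 0
            while i < len(seq) and seq[i] is tr.trigger:
                i += 1
                n += 1
            if n == 0 and not tr.optional:
                if tr.trigger in seq[i:]:
                    diags.append(
                        Diagnostic("error", "event order violates protocol")
                    )
                    return diags
                diags.append(
                    Diagnostic(
                        "error",
                        f"no {tr.state.value} state reachable: missing "
                        f"{tr.trigger.value} event",
                    )
                )
            continue
        if i < len(seq) and seq[i] is tr.trigger:
            i += 1
        elif tr.optional:
            continue
        elif tr.trigger in seq[i:]:
            diags.append(Diagnostic("error", "event order violates protocol"))
            return diags
        else:
            diags.append(
                Diagnostic(
                    "error",
                    f"no {tr.state.value} state reachable: missing "
                    f"{tr.trigger.value} event",
                )
            )
    if i < len(seq):
        extra = ", ".join(r.value for r in seq[i:])
        diags.append(
            Diagnostic(
                "error",
                f"events not consumed by protocol (out of order or foreign): {extra}",
            )
        )
    return diags
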