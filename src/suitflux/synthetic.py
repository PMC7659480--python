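"""Synthetic oxygraph chamber runs with known ground truth.

The simulator integrates the chamber oxygen balance

    dC/dt = -( rho * j_state(t) + a + b * C ) / 1000      [µM/s]

where ``rho = cell_count / volume`` (10^6 cells per mL), ``j_state`` is the
cell respiration of the current respiratory state in pmol/(s·10^6 cells)
relaxing exponentially (time constant ``transition_tau``) to each new
plateau after its titration event, and ``a + b·C`` is the linear-in-O2
instrumental background in pmol/(s·mL).  Between samples the ODE is linear
with exponential forcing, so it is integrated with its exact closed form —
no numeric stepping error.  Gaussian sensor noise is added to the sampled
concentration only; flux noise then arises through differentiation, as in
the real instrument.

Presets encode the study conditions of the control and toxin-treated
(MPP+, a complex I inhibitor) groups.  Only the ratio structure is
anchored (LEAK/ETS 0.19 vs 0.31, state coupling efficiencies 63/78/80/69%
vs 28/65/68/53%, treated ETS depressed by 62.7%, CII-linked ETS fraction
raised by 81%, SCF 0.49 vs 0.52); the absolute flux scale (control ETS =
100 pmol/(s·10^6 cells) after residual correction) is an invented default,
chosen only to be a plausible oxygraph magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import (
    ChamberConfig,
    Diagnostic,
    OxygenTrace,
    ProtocolDefinition,
    Reagent,
    RunRecord,
    State,
    TitrationEvent,
    builtin_protocol,
)

__all__ = ["SimulationTruth", "simulate_run", "preset", "simulate_cohort"]

_MAX_SEED = 2**31 - 1


@dataclass
class SimulationTruth:
    """Ground truth for one simulated run.

    ``fluxes`` holds the *raw* (residual-inclusive) plateau respiration per
    state in pmol/(s·10^6 cells); ``ets_steps`` the raw plateau for each
    CCCP titration step in order.  ``corrected`` exposes the residual-
    corrected values the pipeline should recover.
    """

    fluxes: dict[State, float]
    ets_steps: tuple[float, ...] = ()
    events: tuple[TitrationEvent, ...] = ()
    chamber: ChamberConfig = field(
        default_factory=lambda: ChamberConfig(cell_count=2.0)
    )
    transition_tau: float = 15.0  # s, mixing/response kinetics
    noise_sd: float = 0.2  # µM, sensor noise on concentration
    initial_o2: float = 180.0  # µM
    duration: float = 2400.0  # s
    sample_interval: float = 2.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        self.fluxes = {State(s): float(v) for s, v in self.fluxes.items()}
        if any(v < 0 for v in self.fluxes.values()) or any(
            v < 0 for v in self.ets_steps
        ):
            raise ValueError("state fluxes must be >= 0")
        if not self.initial_o2 > 0:
            raise ValueError("initial_o2 must be > 0")
        if self.transition_tau < 0:
            raise ValueError("transition_tau must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def rox(self) -> float:
        return self.fluxes.get(State.ROX, 0.0)

    @property
    def corrected(self) -> dict[State, float]:
        """Residual-corrected truth fluxes, ETS from the maximal CCCP step."""
        out = {s: v - self.rox for s, v in self.fluxes.items()}
        if self.ets_steps:
            out[State.ETS] = max(self.ets_steps) - self.rox
        out[State.ROX] = 0.0
        return out

    def truth_fcr(self, state: State) -> float:
        c = self.corrected
        return c[State(state)] / c[State.ETS]


def _target_flux(
    truth: SimulationTruth, protocol: ProtocolDefinition
) -> list[tuple[float, float]]:
    """(event time, target plateau j_cell) for each event, in order."""
    state_by_trigger = {t.trigger: t.state for t in protocol.transitions}
    targets = []
    cccp_step = 0
    for ev in truth.events:
        st = state_by_trigger[ev.reagent]
        if st is State.ETS:
            j = truth.ets_steps[min(cccp_step, len(truth.ets_steps) - 1)]
            cccp_step += 1
        else:
            j = truth.fluxes[st]
        targets.append((ev.time, j))
    return targets


def _integrate_interval(
    t_rel: np.ndarray,
    c0: float,
    j_target: float,
    j_jump: float,
    tau: float,
    rho: float,
    a: float,
    b: float,
) -> np.ndarray:
    """Exact solution of C' = -beta*C - (F0 + F1*exp(-u/tau)) on u = t_rel.

    ``j_jump`` is the excess respiration at the interval start (previous
    flux minus new target) decaying with ``tau``.
    """
    beta = b / 1000.0
    f0 = (rho * j_target + a) / 1000.0
    f1 = (rho * j_jump) / 1000.0
    u = t_rel
    eb = np.exp(-beta * u)
    if beta == 0.0:
        phi0 = u
    else:
        phi0 = (1.0 - eb) / beta
    if f1 == 0.0 or tau == 0.0:
        phi1 = np.zeros_like(u)
    else:
        k = 1.0 / tau
        if np.isclose(beta, k):
            phi1 = u * eb
        else:
            phi1 = (np.exp(-k * u) - eb) / (beta - k)
    return c0 * eb - f0 * phi0 - f1 * phi1


def simulate_run(
    truth: SimulationTruth,
    protocol: ProtocolDefinition,
    sample_id: str = "sim",
    group: str = "control",
) -> RunRecord:
    """Integrate one chamber run and return it as a RunRecord.

    Deterministic given ``truth.seed``.  If the chamber oxygen is depleted
    before the protocol completes, the concentration is floored at 0 and a
    warning diagnostic is attached to the run.
    """
    rho = truth.chamber.cell_count / truth.chamber.volume
    a, b = truth.chamber.background_a, truth.chamber.background_b
    tau = truth.transition_tau

    n = int(round(truth.duration / truth.sample_interval)) + 1
    time = np.arange(n) * truth.sample_interval
    conc = np.empty(n)

    targets = _target_flux(truth, protocol)
    boundaries = [0.0] + [t for t, _ in targets] + [truth.duration]
    plateaus = [truth.fluxes[State.ROUTINE]] + [j for _, j in targets]

    c_edge = truth.initial_o2
    j_edge = plateaus[0]  # actual respiration at the running interval edge
    for k in range(len(plateaus)):
        t_a, t_b = boundaries[k], boundaries[k + 1]
        j_tgt = plateaus[k]
        j_jump = j_edge - j_tgt
        sel = (time >= t_a) & (time < t_b) if k + 1 < len(plateaus) else (
            time >= t_a
        )
        u = time[sel] - t_a
        conc[sel] = _integrate_interval(u, c_edge, j_tgt, j_jump, tau, rho, a, b)
        du = t_b - t_a
        c_edge = float(
            _integrate_interval(np.array([du]), c_edge, j_tgt, j_jump, tau, rho, a, b)[0]
        )
        j_edge = j_tgt + (j_jump * np.exp(-du / tau) if tau > 0 else 0.0)

    warnings: list[Diagnostic] = []
    if np.any(conc <= 0):
        warnings.append(
            Diagnostic(
                "warning",
                "chamber oxygen depleted before the protocol completed; "
                "concentration floored at 0",
            )
        )
        conc = np.maximum(conc, 0.0)

    rng = np.random.default_rng(truth.seed)
    if truth.noise_sd > 0:
        conc = conc + rng.normal(0.0, truth.noise_sd, size=n)

    trace = OxygenTrace(
        time=time, o2=conc, sample_id=sample_id, chamber_id="sim"
    )
    return RunRecord(
        trace=trace,
        events=list(truth.events),
        chamber=truth.chamber,
        protocol=protocol,
        group=group,
        warnings=warnings,
    )


# --- presets -----------------------------------------------------------------

_ROX_RAW = 5.0  # residual oxygen consumption, pmol/(s·10^6 cells), invented

# Control group, residual-corrected levels derived from the anchored ratio
# structure at an invented scale of ETS = 100:
#   LEAK/ETS = 0.19; coupling ROUTINE 63%, OXPHOS 78%, CI-OXPHOS 69%
#   (state = LEAK / (1 - coupling)); CII-linked ETS fraction 0.25.
_CTRL_E = 100.0
_CTRL_L = 0.19 * _CTRL_E
_CONTROL = {
    State.ROUTINE: _CTRL_L / (1 - 0.63),
    State.LEAK: _CTRL_L,
    State.OXPHOS_CI: _CTRL_L / (1 - 0.69),
    State.OXPHOS: _CTRL_L / (1 - 0.78),
    State.ETS: _CTRL_E,
    State.ETS_CII: 0.25 * _CTRL_E,
    State.ROX: 0.0,  # corrected by definition
}

# Treated group: ETS depressed by 62.7%; LEAK/ETS = 0.31; coupling ROUTINE
# 28%, OXPHOS 65%, CI-OXPHOS 53%; CII-linked ETS fraction raised by 81%.
_MPP_E = _CTRL_E * (1 - 0.627)
_MPP_L = 0.31 * _MPP_E
_MPP = {
    State.ROUTINE: _MPP_L / (1 - 0.28),
    State.LEAK: _MPP_L,
    State.OXPHOS_CI: _MPP_L / (1 - 0.53),
    State.OXPHOS: _MPP_L / (1 - 0.65),
    State.ETS: _MPP_E,
    State.ETS_CII: 0.25 * 1.81 * _MPP_E,
    State.ROX: 0.0,
}

# Complex II substrate control factors (CII-OXPHOS over paired convergent
# OXPHOS): 0.49 control, 0.52 treated.
_SCF = {"control": 0.49, "mpp_treated": 0.52}
_CORRECTED = {"control": _CONTROL, "mpp_treated": _MPP}

_MAIN_SCHEDULE = (
    (300.0, Reagent.DIG),
    (600.0, Reagent.G),
    (900.0, Reagent.ADP),
    (1200.0, Reagent.S),
    (1500.0, Reagent.CCCP),
    (1650.0, Reagent.CCCP),
    (1800.0, Reagent.ROT),
    (2100.0, Reagent.AMA),
)
_CII_SCHEDULE = (
    (300.0, Reagent.DIG),
    (600.0, Reagent.ROT),
    (900.0, Reagent.ADP),
    (1200.0, Reagent.S),
    (1500.0, Reagent.MAL),
)


def preset(
    name: str,
    protocol: str = "SUIT_MAIN",
    noise_sd: float = 0.2,
    seed: int = 0,
) -> SimulationTruth:
    """Ground truth for the ``control`` or ``mpp_treated`` study condition.

    ``protocol`` selects the main respiratory-state run (``SUIT_MAIN``) or
    the rotenone-first complex II run (``SUIT_CII``).  The first CCCP step
    under-titrates at 90% of the ETS plateau; the second reaches it, so the
    maximum-across-steps rule locates the true capacity.
    """
    if name not in _CORRECTED:
        raise ValueError(
            f"unknown preset {name!r}; valid presets are control, mpp_treated"
        )
    corr = _CORRECTED[name]
    if protocol == "SUIT_MAIN":
        raw = {s: v + _ROX_RAW for s, v in corr.items() if s is not State.ETS}
        raw[State.ROX] = _ROX_RAW
        ets = corr[State.ETS]
        return SimulationTruth(
            fluxes=raw,
            ets_steps=(0.9 * ets + _ROX_RAW, ets + _ROX_RAW),
            events=tuple(TitrationEvent(t, r) for t, r in _MAIN_SCHEDULE),
            noise_sd=noise_sd,
            seed=seed,
        )
    if protocol == "SUIT_CII":
        oxphos_cii = _SCF[name] * corr[State.OXPHOS]
        raw = {
            State.ROUTINE: corr[State.ROUTINE] + _ROX_RAW,
            State.LEAK: corr[State.LEAK] + _ROX_RAW,
            State.NULL: _ROX_RAW,  # rotenone+ADP give no response above residual
            State.OXPHOS_CII: oxphos_cii + _ROX_RAW,
            State.ROX: _ROX_RAW,  # post-malonate baseline
        }
        return SimulationTruth(
            fluxes=raw,
            events=tuple(TitrationEvent(t, r) for t, r in _CII_SCHEDULE),
            duration=1800.0,
            noise_sd=noise_sd,
            seed=seed,
        )
    raise ValueError(f"unknown protocol {protocol!r}; use SUIT_MAIN or SUIT_CII")


def simulate_cohort(
    preset_name: str,
    n_runs: int,
    between_run_cv: float = 0.15,
    seed: int = 0,
    protocol: str = "SUIT_MAIN",
    noise_sd: float = 0.2,
    state_jitter_cv: float = 0.03,
    group: str | None = None,
    return_truth: bool = False,
):
    """Simulate a cohort of biological replicates of one preset.

    Between-run variability is multiplicative lognormal applied *jointly*
    to all residual-corrected fluxes (``between_run_cv``), which preserves
    every ratio metric, plus small independent per-state lognormal jitter
    (``state_jitter_cv``) that perturbs the ratios realistically.  Seeded
    and fully reproducible.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    base = preset(preset_name, protocol=protocol, noise_sd=noise_sd)
    proto = builtin_protocol(protocol)
    group = group if group is not None else preset_name
    rng = np.random.default_rng(seed)

    runs: list[RunRecord] = []
    truths: list[SimulationTruth] = []
    for i in range(n_runs):
        scale = _lognormal_unit_mean(rng, between_run_cv)
        fluxes = {}
        for s, raw in base.fluxes.items():
            corr = raw - base.rox
            jit = _lognormal_unit_mean(rng, state_jitter_cv)
            fluxes[s] = corr * scale * jit
        rox = base.rox * scale * _lognormal_unit_mean(rng, state_jitter_cv)
        fluxes = {s: v + rox for s, v in fluxes.items()}
        fluxes[State.ROX] = rox
        if base.ets_steps:
            ets_jit = scale * _lognormal_unit_mean(rng, state_jitter_cv)
            ets_steps = tuple(
                (v - base.rox) * ets_jit + rox for v in base.ets_steps
            )
        else:
            ets_steps = ()
        truth = replace(
            base,
            fluxes=fluxes,
            ets_steps=ets_steps,
            seed=int(rng.integers(_MAX_SEED)),
        )
        run = simulate_run(
            truth,
            proto,
            sample_id=f"{preset_name}-{i:02d}",
            group=group,
        )
        runs.append(run)
        truths.append(truth)
    if return_truth:
        return runs, truths
    return runs


def _lognormal_unit_mean(rng: np.random.Generator, cv: float) -> float:
    """Lognormal multiplier with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)))
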