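# Methods

This note records the measurement model, the analysis choices and their
defaults, the simulator's scope, and the numerical decisions behind
`suitflux`.

## Measurement model

A closed oxygraph chamber of volume `V` (mL) holds `N` million cells in
respiration medium. The sensor reports dissolved oxygen `C(t)` in µM on a
regular grid (default 2 s). Oxygen mass balance:

```
dC/dt = -( rho * j_state(t) + a + b*C ) / 1000,      rho = N / V
```

where `j_state(t)` is the per-million-cells respiration (pmol O2/(s·10^6
cells)) of the current respiratory state and `a + b*C` is the calibrated
linear instrumental background (electrode consumption plus back-diffusion,
pmol/(s·mL)). The factor 1000 converts pmol/(s·mL) to µM/s. The analysis
inverts this model step by step:

1. **Derivative.** `j_total = -dC/dt * 1000`, respiration positive. The
   slope is estimated independently on each inter-event segment so that
   smoothing never averages across a titration step.
2. **Background.** `j_sample = j_total - (a + b*C)`.
3. **Normalization.** `j_cell = j_sample * V / N`.
4. **Segmentation.** Events map to states via the protocol's transition
   table; ROUTINE spans the acquisition start to the first addition.
5. **Marks.** One steady-state mark per state; ETS is the maximum plateau
   over CCCP titration steps; every state is corrected by subtracting the
   residual (ROX) plateau, with `corrected(ROX) == 0` by construction.

## Protocols

Two built-in `ProtocolDefinition`s describe the titration grammar:

- `SUIT_MAIN`: DIG → LEAK, G → LEAK (optional), ADP → OXPHOS_CI,
  S → OXPHOS, CCCP (repeatable) → ETS, ROT → ETS_CII, AMA → ROX.
  Reference state for ratios: ETS.
- `SUIT_CII`: DIG → LEAK, ROT and ADP → a null (non-respiring beyond
  residual) state, S → OXPHOS_CII, malonate → ROX. Its OXPHOS_CII plateau
  is divided by the paired main-protocol OXPHOS to give the substrate
  control factor (SCF).

Default doses follow common practice for intact/permeabilized cell SUIT
runs (5 mM pyruvate, 2 mM malate, 10 mM glutamate, 2.5 mM ADP, 10 mM
succinate, 0.5 µM CCCP per step, 2 µM rotenone, 2.5 µM antimycin A,
5 mM malonate, ~4 µM digitonin); they are metadata only and do
not affect computation.

`validate_run` checks event ordering against the transition table and
returns diagnostics (e.g. "no ROX state reachable: missing AMA") instead of
failing deep inside the pipeline.

## Analysis parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `derivative_window_s` | 20 s | 11 samples at 2 s spacing: enough averaging to tame sensor noise, short against the 300 s state spans and the 15 s response time, so plateau curvature bias stays negligible. |
| `derivative_method` | sliding regression | local least-squares line per window; a Savitzky–Golay first derivative is available and agrees on smooth traces. |
| `settle_s` | 60 s | four response time-constants of a typical stirred 2 mL chamber; the injection/mixing transient has decayed to < 2 % of the step by then. |
| `window_s` (steady-state mark) | `None` = full post-settle plateau | with white sensor noise the variance of a fitted slope falls with the cube of the marked span, so discarding plateau data costs precision for no robustness gain. A fixed-length minimum-variance window (latest on ties) is available for drifting plateaus. |
| `ets_rule` | max over CCCP steps | uncoupler over-titration depresses respiration, so the optimal step is the largest plateau, not the last. |
| negative corrected fluxes | warn, never clamp | clamping at zero would bias every ratio built on the corrected fluxes; negative values are legitimate noise outcomes near the ROX level. |
| t-test variant | Student (Welch optional) | matched to the small, similarly sized and similarly dispersed groups typical of oxygraph studies. |
| significance stars | 0.05 / 0.01 / 0.001 | conventional thresholds; percent changes reported to one decimal. |

Two further mark details matter for precision:

- **Re-entered states are marked on their latest sub-segment.** When a later
  addition re-enters the same state (glutamate under `SUIT_MAIN`, ADP after
  rotenone under `SUIT_CII`), the mark is placed after the *last* addition,
  so it never spans an intervening mixing transient.
- **Trailing half derivative-window exclusion.** Within half a derivative
  window of a segment's end the slope estimate is one-sided (no samples
  beyond the next titration exist), which inflates its variance; marks use
  interior, fully windowed estimates only.

## Metrics

With `c(s)` the ROX-corrected flux of state `s`:

- `fcr(s) = c(s) / c(ETS)`; `net_fcr(s) = fcr(s) - fcr(LEAK)`
- `coupling_efficiency(s) = 1 - c(LEAK) / c(s)` for ROUTINE, OXPHOS_CI,
  OXPHOS and ETS
- `respiratory_reserve = (c(OXPHOS) - c(ROUTINE)) / c(ETS)` by default;
  `(c(ETS) - c(ROUTINE)) / c(ETS)` selectable
- `cii_ets_fcr = c(ETS_CII) / c(ETS)`
- `scf_cii = c(OXPHOS_CII) / c(OXPHOS of the paired main run)`, paired by
  `sample_id`

Note one subtlety the acceptance tests encode: under a global-inhibition
contrast the *absolute* spare capacity `c(OXPHOS) - c(ROUTINE)` can
collapse while the ETS-normalized reserve ratio rises, because ROUTINE
falls relatively faster than OXPHOS. Sign expectations should be attached
to the absolute difference, not the normalized ratio.

## The simulator

`simulate_run` integrates the mass-balance ODE exactly. Respiration relaxes
exponentially to each new state's plateau with time constant
`transition_tau` (default 15 s, a stirred-chamber response time); within
each inter-event interval the ODE with forcing
`target + jump*exp(-t/tau)` and linear background has a closed form, which
is chained interval by interval. There is no numerical integration error;
the test suite checks agreement with an independent `solve_ivp` oracle and
a mass-balance identity.

Gaussian sensor noise (`noise_sd`, default 0.2 µM) is added to the
concentration samples only — the underlying kinetics stay exact — and the
trace floors at 0 µM with a depletion warning.

**Presets.** Two `SimulationTruth` presets encode the flux structure of a
vehicle-control and an MPP+-like complex-I-poisoned cell population. The
absolute scale is arbitrary (control ETS capacity set to 100
pmol/(s·10^6 cells)); all state plateaus are derived from the preset's
ratio structure: control LEAK FCR 0.19 vs treated 0.31, couplings
(ROUTINE 0.63 vs 0.28, OXPHOS_CI 0.69 vs 0.53, OXPHOS 0.78 vs 0.65,
ETS 0.80 vs 0.68), a 62.7 % ETS depression, CII-linked ETS share up
~80 %, and SCF 0.49 vs 0.52. The residual (ROX) plateau is 5 in the same
units. The two CCCP steps are 0.9× and 1.0× of capacity, exercising the
max-plateau rule.

**Cohorts.** `simulate_cohort` draws per-run truths around a preset:
a joint lognormal scale factor (`between_run_cv`, default 0.15) multiplies
all plateaus of a run — preserving its ratio structure, as biological
variation in cell mass/content does — plus independent per-state lognormal
jitter (`state_jitter_cv`, default 0.03) for plateau-level measurement
idiosyncrasy. Both lognormals are unit-mean. All randomness flows from a
single integer seed through `numpy.random.default_rng`.

**What the simulator does not emulate:** sensor drift and recalibration
error, injection spike artifacts, chamber reoxygenation or leaks, oxygen
diffusion into electrode membranes, oxygen-dependence of respiration near
depletion, pH or temperature excursions, and nonlinear (beyond `a + b*C`)
background. Background defaults to zero in the presets; the analysis-side
correction is exercised separately in tests.

## Numerical choices

- The sliding regression is vectorized with prefix sums over re-centered
  time, giving O(n) slopes per segment; windows are centered where possible.
  At segment ends, where only one-sided windows exist, a local line read
  away from its centroid is biased on curved traces, so those few points are
  refit with a local quadratic evaluated at the sample.
- Steady-state marks require ≥ 5 samples; `derive_flux` rejects smoothing
  windows spanning fewer than 5 samples rather than silently widening them.
- Group summaries use the sample standard deviation (ddof = 1), reported as
  absent for n = 1; comparisons require n ≥ 2 per group.
- CSV round trips are exact for the JSON run format (bit-identical arrays)
  and numerically faithful for the tabular formats.

## Limitations

- The plateau model assumes states reach steady state within the settle
  window; strongly drifting plateaus (e.g. substrate exhaustion) would need
  the fixed-window minimum-variance mark and shorter windows.
- The background calibration `(a, b)` must be supplied per chamber; it is
  not estimated from the run itself.
- The statistics module implements two-sample t-tests only; repeated
  measures and multi-group designs are out of scope.
- Simulated noise is white and homoscedastic; correlated sensor noise would
  lower the effective information content of a plateau relative to the
  variance argument used for the default mark window.
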