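"""Trace differentiation, background correction and state-flux extraction."""

import numpy as np
import pytest

import suitflux as sf
from suitflux.flux import mark_steady_state, segment_states
from suitflux.protocol import Reagent, State


def _trace(conc, dt=1.0):
    time = np.arange(len(conc)) * dt
    return sf.OxygenTrace(time=time, o2=np.asarray(conc, dtype=float))


@pytest.mark.parametrize("method", ["sliding-regression", "savitzky-golay"])
class TestDeriveFlux:
    def test_linear_decay_gives_constant_flux(self, method):
        t = np.arange(0, 300.0)
        fx = sf.derive_flux(_trace(100 - 0.1 * t), 20.0, method)
        assert np.allclose(fx.j_total, 100.0, atol=1e-8)

    def test_constant_concentration_gives_zero_flux(self, method):
        fx = sf.derive_flux(_trace(np.full(200, 150.0)), 20.0, method)
        assert np.allclose(fx.j_total, 0.0, atol=1e-9)

    def test_exponential_decay_matches_analytic_derivative(self, method):
        t = np.arange(0, 600.0)
        fx = sf.derive_flux(_trace(100 * np.exp(-0.001 * t)), 20.0, method)
        analytic = 100 * 0.001 * np.exp(-0.001 * t) * 1000
        assert np.max(np.abs(fx.j_total - analytic) / analytic) < 0.01

    def test_window_does_not_cross_events(self, method):
        # step change in slope exactly at the event: each side stays exact
        t = np.arange(0, 200.0)
        conc = np.where(t < 100, 180 - 0.05 * t, 175 - 0.2 * (t - 100))
        fx = sf.derive_flux(_trace(conc), 20.0, method, event_times=[100.0])
        assert np.allclose(fx.j_total[t < 100], 50.0, atol=1e-6)
        assert np.allclose(fx.j_total[t >= 100], 200.0, atol=1e-6)


def test_derive_flux_rejects_tiny_window():
    with pytest.raises(ValueError, match="5 samples"):
        sf.derive_flux(_trace(np.linspace(100, 90, 50), dt=10.0), 20.0)


def test_derive_flux_rejects_unknown_method():
    with pytest.raises(ValueError, match="method"):
        sf.derive_flux(_trace(np.linspace(100, 90, 50)), 20.0, "spline")


class TestBackgroundAndNormalization:
    def test_zero_background_is_identity(self):
        trace = _trace(np.full(100, 100.0))
        fx = sf.derive_flux(trace, 20.0)
        out = sf.subtract_background(fx, trace, sf.ChamberConfig(cell_count=1.0))
        assert np.array_equal(out.j_sample, fx.j_total)

    def test_constant_offset_and_linear_term(self):
        trace = _trace(np.full(100, 100.0))
        fx = sf.FluxSeries(time=trace.time, j_total=np.full(100, 102.0))
        out = sf.subtract_background(
            fx, trace, sf.ChamberConfig(cell_count=1.0, background_a=2.0)
        )
        assert np.allclose(out.j_sample, 100.0)
        out = sf.subtract_background(
            fx, trace,
            sf.ChamberConfig(cell_count=1.0, background_a=1.0, background_b=0.01),
        )
        assert np.allclose(fx.j_total - out.j_sample, 2.0)  # 1 + 0.01*100

    def test_grid_mismatch_rejected(self):
        trace = _trace(np.full(100, 100.0))
        fx = sf.FluxSeries(time=trace.time[:-1], j_total=np.zeros(99))
        with pytest.raises(ValueError, match="grid"):
            sf.subtract_background(fx, trace, sf.ChamberConfig(cell_count=1.0))

    @pytest.mark.parametrize("cells,factor", [(2.0, 1.0), (1.0, 2.0), (4.0, 0.5)])
    def test_per_cell_normalization(self, cells, factor):
        fx = sf.FluxSeries(
            time=np.arange(10.0), j_total=np.full(10, 100.0),
            j_sample=np.full(10, 100.0),
        )
        out = sf.normalize_per_cells(fx, sf.ChamberConfig(cell_count=cells, volume=2.0))
        assert np.allclose(out.j_cell, 100.0 * factor)

    def test_normalization_requires_background_step(self):
        fx = sf.FluxSeries(time=np.arange(10.0), j_total=np.zeros(10))
        with pytest.raises(ValueError, match="j_sample"):
            sf.normalize_per_cells(fx, sf.ChamberConfig(cell_count=1.0))


class TestSegmentation:
    def test_main_protocol_maps_events_to_states(self, suit_main):
        time = np.arange(0.0, 2401.0, 2.0)
        trace = sf.OxygenTrace(time=time, o2=np.linspace(180, 60, time.size))
        schedule = [
            (300, Reagent.DIG), (600, Reagent.G), (900, Reagent.ADP),
            (1200, Reagent.S), (1500, Reagent.CCCP), (1650, Reagent.CCCP),
            (1800, Reagent.ROT), (2100, Reagent.AMA),
        ]
        run = sf.RunRecord(
            trace=trace,
            events=[sf.TitrationEvent(float(t), r) for t, r in schedule],
            chamber=sf.ChamberConfig(cell_count=2.0),
            protocol=suit_main,
        )
        segs = segment_states(run)
        assert segs == [
            (State.ROUTINE, 0.0, 300.0),
            (State.LEAK, 300.0, 900.0),     # glutamate keeps LEAK open
            (State.OXPHOS_CI, 900.0, 1200.0),
            (State.OXPHOS, 1200.0, 1500.0),
            (State.ETS, 1500.0, 1650.0),    # CCCP candidates stay separate
            (State.ETS, 1650.0, 1800.0),
            (State.ETS_CII, 1800.0, 2100.0),
            (State.ROX, 2100.0, 2400.0),
        ]

    def test_cii_protocol_emits_no_ci_oxphos(self, suit_cii):
        run = sf.simulate_run(
            sf.preset("control", protocol="SUIT_CII", noise_sd=0.0), suit_cii
        )
        states = [s for s, _, _ in segment_states(run)]
        assert State.OXPHOS_CI not in states
        assert states == [State.ROUTINE, State.LEAK, State.NULL,
                          State.OXPHOS_CII, State.ROX]

    def test_zero_events_is_a_single_routine_segment(self, suit_main):
        trace = sf.OxygenTrace(time=np.arange(100.0), o2=np.full(100, 150.0))
        run = sf.RunRecord(trace=trace, events=[],
                           chamber=sf.ChamberConfig(cell_count=1.0),
                           protocol=suit_main)
        assert segment_states(run) == [(State.ROUTINE, 0.0, 99.0)]

    def test_unsatisfied_protocol_raises(self, suit_main):
        trace = sf.OxygenTrace(time=np.arange(100.0), o2=np.full(100, 150.0))
        run = sf.RunRecord(
            trace=trace, events=[sf.TitrationEvent(50.0, Reagent.ROT)],
            chamber=sf.ChamberConfig(cell_count=1.0), protocol=suit_main,
        )
        with pytest.raises(ValueError, match="protocol"):
            segment_states(run)


class TestSteadyStateMark:
    @staticmethod
    def _series(values, dt=2.0):
        t = np.arange(len(values)) * dt
        return sf.FluxSeries(time=t, j_total=np.asarray(values, float),
                             j_sample=np.asarray(values, float),
                             j_cell=np.asarray(values, float))

    def test_constant_segment_recovers_constant(self):
        fx = self._series(np.full(200, 42.0))
        mark = mark_steady_state(fx, (State.LEAK, 0.0, 398.0), settle_s=60.0)
        assert mark.mean_flux == pytest.approx(42.0)
        assert mark.sd_flux == 0.0

    def test_exponential_approach_recovers_plateau(self):
        t = np.arange(0, 400.0, 2.0)
        j = 100.0 * (1 - np.exp(-t / 30.0))  # tau 30 s, plateau 100
        fx = self._series(j)
        mark = mark_steady_state(fx, (State.OXPHOS, 0.0, 398.0),
                                 settle_s=120.0, window_s=60.0)
        assert abs(mark.mean_flux - 100.0) / 100.0 < 0.01

    def test_minimum_variance_window_avoids_transient(self):
        t = np.arange(0, 400.0, 2.0)
        j = np.where(t < 200, np.sin(t) * 5 + 50, 50.0)  # noisy then flat
        mark = mark_steady_state(self._series(j), (State.ETS, 0.0, 398.0),
                                 settle_s=0.0, window_s=60.0)
        assert mark.t_start >= 200.0
        assert mark.sd_flux == 0.0

    def test_too_short_segment_suggests_smaller_windows(self):
        fx = self._series(np.full(30, 10.0))
        with pytest.raises(ValueError, match="reduce"):
            mark_steady_state(fx, (State.LEAK, 0.0, 58.0),
                              settle_s=40.0, window_s=60.0)


class TestStateFluxes:
    def test_zero_noise_recovery_within_2pct(self, control_table_clean,
                                             control_truth_clean):
        truth = control_truth_clean.corrected
        for state, value in control_table_clean.corrected.items():
            if state is State.ROX:
                continue
            assert value == pytest.approx(truth[state], rel=0.02), state

    def test_rox_corrected_rox_is_exactly_zero(self, control_table_clean):
        assert control_table_clean.corrected[State.ROX] == 0.0

    def test_correction_subtracts_rox_everywhere(self, control_table_clean):
        t = control_table_clean
        for state in t.raw:
            if state is State.ROX:
                continue
            assert t.corrected[state] == pytest.approx(
                t.raw[state] - t.rox_value
            )

    def test_ets_is_max_over_cccp_steps(self, suit_main):
        truth = sf.preset("control", noise_sd=0.0)
        # first step overshoots the second: max rule must pick it
        truth.ets_steps = (125.0, 115.0)
        table = sf.state_fluxes(sf.simulate_run(truth, suit_main))
        assert table.raw[State.ETS] == pytest.approx(125.0, rel=0.02)

    def test_flux_linearity_in_slope_scale(self, suit_main):
        base = sf.preset("control", noise_sd=0.0)
        k = 0.7  # < 1 so the scaled run cannot deplete the chamber
        scaled = sf.preset("control", noise_sd=0.0)
        scaled.fluxes = {s: k * v for s, v in base.fluxes.items()}
        scaled.ets_steps = tuple(k * v for v in base.ets_steps)
        t1 = sf.state_fluxes(sf.simulate_run(base, suit_main))
        t2 = sf.state_fluxes(sf.simulate_run(scaled, suit_main))
        for state in t1.raw:
            assert t2.raw[state] == pytest.approx(k * t1.raw[state], rel=1e-6)

    def test_cell_count_invariance(self, control_run_clean):
        import dataclasses

        run2 = sf.RunRecord(
            trace=control_run_clean.trace,
            events=control_run_clean.events,
            chamber=dataclasses.replace(control_run_clean.chamber,
                                        cell_count=2 * control_run_clean.chamber.cell_count),
            protocol=control_run_clean.protocol,
        )
        t1 = sf.state_fluxes(control_run_clean)
        t2 = sf.state_fluxes(run2)
        for state in t1.raw:
            assert t2.raw[state] == pytest.approx(0.5 * t1.raw[state])

    def test_negative_corrected_flux_warned_not_clamped(self, suit_main):
        truth = sf.preset("control", noise_sd=0.0)
        truth.fluxes[State.ROX] = truth.fluxes[State.LEAK] + 5.0  # rox above leak
        table = sf.state_fluxes(sf.simulate_run(truth, suit_main))
        assert table.corrected[State.LEAK] < 0
        assert any("negative" in w.message for w in table.warnings)

    def test_background_round_trip(self, suit_main):
        # simulate with a nonzero background, analyze with the same parameters
        chamber = sf.ChamberConfig(cell_count=2.0, background_a=2.0,
                                   background_b=0.02)
        truth = sf.preset("control", noise_sd=0.0)
        truth.chamber = chamber
        table = sf.state_fluxes(sf.simulate_run(truth, suit_main))
        for state, value in truth.corrected.items():
            if state is State.ROX:
                continue
            assert table.corrected[state] == pytest.approx(value, rel=0.02)
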