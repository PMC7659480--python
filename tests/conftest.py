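import numpy as np
import pytest

import suitflux as sf


@pytest.fixture(scope="session")
def suit_main():
    return sf.builtin_protocol("SUIT_MAIN")


@pytest.fixture(scope="session")
def suit_cii():
    return sf.builtin_protocol("SUIT_CII")


@pytest.fixture(scope="session")
def control_truth_clean():
    return sf.preset("control", noise_sd=0.0)


@pytest.fixture(scope="session")
def control_run_clean(control_truth_clean, suit_main):
    return sf.simulate_run(control_truth_clean, suit_main, sample_id="c0")


@pytest.fixture(scope="session")
def control_table_clean(control_run_clean):
    return sf.state_fluxes(control_run_clean)


def make_table(
    routine=60.0,
    leak=19.0,
    oxphos_ci=70.0,
    oxphos=100.0,
    ets=120.0,
    ets_cii=45.0,
    rox=5.0,
    sample_id="t0",
    group="control",
):
    """Hand-built StateFluxTable from raw plateau fluxes (rox included)."""
    raw = {
        sf.State.ROUTINE: routine,
        sf.State.LEAK: leak,
        sf.State.OXPHOS_CI: oxphos_ci,
        sf.State.OXPHOS: oxphos,
        sf.State.ETS: ets,
        sf.State.ETS_CII: ets_cii,
        sf.State.ROX: rox,
    }
    corrected = {s: v - rox for s, v in raw.items()}
    corrected[sf.State.ROX] = 0.0
    return sf.StateFluxTable(
        sample_id=sample_id,
        group=group,
        protocol_name="SUIT_MAIN",
        raw=raw,
        corrected=corrected,
        sd={s: 0.0 for s in raw},
        windows={s: (0.0, 1.0) for s in raw},
        rox_value=rox,
    )


@pytest.fixture
def flux_table():
    return make_table()
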