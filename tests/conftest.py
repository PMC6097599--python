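import numpy as np
import pytest

from endophys import (
    assemble_record,
    correct_series,
    find_steady_window,
    fit_baseline,
    records_to_frame,
)
from endophys.synthetic_data import (
    ChamberConfig,
    PRESETS,
    draw_individuals,
    generate_cohort,
    simulate_trace,
    steady_physiology,
)


@pytest.fixture()
def quiet_chamber():
    """Noise- and drift-free chamber for deterministic round trips."""
    return ChamberConfig(
        o2_noise_sd=0.0,
        co2_noise_sd=0.0,
        rh_noise_sd=0.0,
        t_noise_sd=0.0,
        tb_noise_sd=0.0,
        o2_drift_per_h=0.0,
        co2_drift_per_h=0.0,
        rh_drift_per_h=0.0,
        animal_s=7200.0,
        hot_animal_s=7200.0,
    )


@pytest.fixture()
def fast_chamber():
    """Default noise but a short (90 min) trial, for quick pipeline tests."""
    return ChamberConfig(animal_s=5400.0, hot_animal_s=5400.0)


@pytest.fixture()
def arid_trial(quiet_chamber):
    """One noise-free trial at thermoneutrality with its generative truth."""
    scenario = PRESETS["arid"]
    indiv = draw_individuals(scenario, np.random.default_rng(1))[0]
    truth = steady_physiology(scenario, indiv, 26.0)
    trace = simulate_trace(truth, quiet_chamber, 0, ta=26.0, mass_g=indiv.mass_g)
    return trace, truth, indiv


def process_trace(trace):
    """Full single-trace pipeline: baseline -> series -> window -> record."""
    baseline = fit_baseline(trace)
    series = correct_series(trace, baseline)
    window = find_steady_window(series)
    return assemble_record(window, trace.meta), window, series


@pytest.fixture(scope="session")
def default_cohort():
    """The full default synthetic cohort (192 traces), processed end to end.

    Session-scoped: generating and processing the cohort takes on the
    order of a minute and several tests score against it.
    Returns ``(records_frame, truth_frame)``.
    """
    traces, truth = generate_cohort(seed=1)
    records = []
    for trace in traces:
        rec, _, _ = process_trace(trace)
        records.append(rec)
    return records_to_frame(records), truth
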