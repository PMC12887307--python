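import numpy as np
import pytest

from cesdyn.synthetic import (
    DomScenario, DomTimePoint, PhaseWindow, PressureScenario,
    gen_dom_peaklists, gen_pressure_experiment,
)


def make_pressure_scenario(**overrides) -> PressureScenario:
    """A small, fast pressure scenario: 2 vials, 6 days, one 15-hPa phase,
    noiseless and uncoupled unless overridden."""
    defaults = dict(
        n_units=2, duration_days=6, dt_s=60.0,
        phase_windows=(PhaseWindow(1, 6, 15.0, 0.0),),
        collapse_window=None, collapse_drop_hpa=0.0,
        temp_diel_amplitude_c=0.0, temp_coupling_hpa_per_c=0.0,
        noise_sd_hpa=0.0, drift_hpa_per_day=0.0, seed=0,
    )
    defaults.update(overrides)
    return PressureScenario(**defaults)


def make_dom_scenario(n_cho=120, n_chno=60, n_chos=20, ppm_noise_sd=0.0,
                      seed=0, **overrides) -> DomScenario:
    """A one-time-point DOM scenario small enough for per-test assignment."""
    mk = lambda d: tuple(d.items())
    mixture = mk({
        "lignin/CRAM-like": 0.45, "aliphatic/peptides": 0.15, "lipids": 0.10,
        "carbohydrates": 0.10, "unsaturated hydrocarbons": 0.05,
        "tannins": 0.10, "aromatic structures": 0.05})
    defaults = dict(
        time_points=(DomTimePoint(
            "t0", mk({"CHO": n_cho, "CHNO": n_chno, "CHOS": n_chos}),
            mixture, target_chemodiversity=4.5),),
        replicates=1, ppm_noise_sd=ppm_noise_sd, seed=seed)
    defaults.update(overrides)
    return DomScenario(**defaults)


@pytest.fixture(scope="session")
def noiseless_pressure():
    scenario = make_pressure_scenario()
    traces, control, truth = gen_pressure_experiment(scenario)
    return scenario, traces, control, truth


@pytest.fixture(scope="session")
def small_dom_study():
    study = gen_dom_peaklists(make_dom_scenario(ppm_noise_sd=0.2, seed=5))
    return study
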