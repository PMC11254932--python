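import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phyllon import budget, synthetic, tracer

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_records() -> pd.DataFrame:
    scenario = synthetic.IncubationScenario(noise_rel_sd=0.0, seed=7)
    return synthetic.gen_incubation(scenario)


@pytest.fixture(scope="session")
def noise_free_scenario() -> synthetic.IncubationScenario:
    return synthetic.IncubationScenario(noise_rel_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noise_free_rates(noise_free_records) -> pd.DataFrame:
    return tracer.estimate_rates(noise_free_records)


@pytest.fixture(scope="session")
def meadow_params() -> dict:
    return {
        "ambient": budget.MeadowParams(ncp=150.0, cn_molar=20.0, leaf_area_index=5e4),
        "vent": budget.MeadowParams(ncp=250.0, cn_molar=22.0, leaf_area_index=5e4),
    }
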