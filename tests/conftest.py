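import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import foodclim as fc

settings.register_profile(
    "det", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def climate12() -> pd.DataFrame:
    """Default-condition climate for a small 12-region panel."""
    return fc.simulate_climate(fc.ClimateGenParams(n_regions=12, seed=11))


@pytest.fixture(scope="session")
def shdi12(climate12) -> pd.DataFrame:
    regions = sorted(climate12["region_id"].unique())
    return fc.simulate_shdi(regions, fc.STUDY_YEARS, seed=12)


@pytest.fixture(scope="session")
def panel12(climate12, shdi12) -> pd.DataFrame:
    """Noisy panel with the published coefficient paths as truth."""
    return fc.simulate_panel(climate12, fc.PanelGenParams(seed=13), shdi12)


@pytest.fixture(scope="session")
def noiseless_panel12(climate12, shdi12) -> pd.DataFrame:
    gen = fc.PanelGenParams(seed=14, noise_sd=0.0)
    return fc.simulate_panel(climate12, gen, shdi12)


@pytest.fixture(scope="session")
def tiny_config() -> fc.PipelineConfig:
    """Six-region pipeline configuration small enough for smoke runs."""
    return fc.PipelineConfig.from_dict(
        {
            "seed": 5,
            "climate": {"n_regions": 6},
            "survey": {"respondents_per_region": 40},
        }
    )
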