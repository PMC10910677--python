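import logging

import numpy as np
import pytest

from qale_smallarea import PipelineConfig, SystemConfig, generate_system, run_pipeline

# the continuity-adjustment log message is expected on sparse fixtures
logging.getLogger("qale_smallarea.sullivan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SystemConfig:
    """A deliberately small system: 16 areas, sparse deaths, modest surveys."""
    return SystemConfig(
        n_areas=16,
        population_range=(2_000, 6_000),
        survey_n_range=(60, 120),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_system(small_config):
    return generate_system(small_config)


@pytest.fixture(scope="session")
def small_pipeline_result(small_system):
    cfg = PipelineConfig(
        deaths=small_system.deaths,
        population=small_system.population,
        reference=small_system.reference_schedule,
        survey=small_system.survey,
        indicators=small_system.indicators,
    )
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def flat_reference():
    """Constant-hazard reference schedule over ages 0..110 (log m = log 0.01)."""
    from qale_smallarea import ReferenceSchedule

    ages = np.arange(0, 111)
    return ReferenceSchedule(sex="M", ages=ages, log_mx=np.full(111, np.log(0.01)))


def make_mortality_input(deaths, exposure, area="A1", sex="M", age_max=110):
    """Grouped 5-year input covering 0..age_max from two aligned arrays."""
    from qale_smallarea import MortalityInput

    groups = [f"{lo}-{lo+4}" for lo in range(0, 90, 5)] + ["90+"]
    return MortalityInput(
        area_id=area, sex=sex, age_groups=groups,
        deaths=np.asarray(deaths, float), exposure=np.asarray(exposure, float),
    )


@pytest.fixture()
def grouped_input_factory():
    return make_mortality_input
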