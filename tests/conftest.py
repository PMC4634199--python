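import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import compmap

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_spec() -> compmap.CohortSpec:
    return compmap.CohortSpec(n_carriers=60, n_controls=40, n_volumes_rest=60)


@pytest.fixture(scope="session")
def truth() -> compmap.GroundTruth:
    return dataclasses.replace(compmap.GroundTruth(), seed=42)


@pytest.fixture(scope="session")
def records(small_spec, truth):
    return compmap.generate_cohort_table(small_spec, truth)


@pytest.fixture(scope="session")
def frame(records):
    return compmap.records_to_frame(records)


@pytest.fixture(scope="session")
def carriers(frame):
    return frame[frame["group"] == "preHD"].reset_index(drop=True)


@pytest.fixture(scope="session")
def task_images(records, small_spec, truth):
    return compmap.generate_task_contrast_images(records, small_spec, truth)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
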