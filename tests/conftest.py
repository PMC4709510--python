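import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import craniometry as cm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return cm.default_schema()


@pytest.fixture(scope="session")
def template():
    return cm.template_skull()


@pytest.fixture(scope="session")
def template_frame(template, schema):
    return cm.build_frame(template, schema)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort, 7 ages x 4 specimens, fixed seed."""
    return cm.sample_cohort(cm.CohortSpec(seed=20160112))


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    table, _ = cm.measure_cohort(small_cohort)
    return table


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q
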