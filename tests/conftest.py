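import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fizsel as fz

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey_dataset() -> fz.CountsDataset:
    """One realistic 10-collection dataset under a sexually antagonistic,
    fluctuating truth with the field survey's sample-size structure."""
    return fz.simulate_counts(fz.preset_scenarios("field_survey", seed=11))


@pytest.fixture(scope="session")
def survey_fit(survey_dataset) -> fz.FitResult:
    return fz.fit_full_model(survey_dataset, g=5, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_state(rng: np.random.Generator) -> fz.PopulationState:
    """A random valid interior adult state."""
    f = rng.dirichlet([2.0, 2.0, 2.0])
    return fz.PopulationState(
        p_m=float(rng.uniform(0.02, 0.98)),
        f_CC=float(f[0]),
        f_CG=float(f[1]),
        f_GG=float(f[2]),
    )
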