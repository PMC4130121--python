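import numpy as np
import pytest
from hypothesis import settings

import clampval as cv

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_results():
    """One full fit of the default 87-subject synthetic study (seeded)."""
    study = cv.ClampStudy.from_synthetic(cv.CohortSpec(seed=42))
    return study.fit(cv.AnalysisConfig(seed=42, bootstrap_B=100))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
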