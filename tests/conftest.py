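import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_brood_table():
    """Hand-built brood table covering every exclusion reason."""
    return pd.DataFrame({
        "female_id": [f"F{i:04d}" for i in range(1, 9)],
        "symbiotype": ["U", "U", "RT", "RT", "RTW1", "RTW1", "RTW12", "RTW123"],
        "mated": [True, True, True, False, True, True, True, True],
        "eggs_laid": [20, 10, 15, 0, 16, 12, 18, 14],
        "eggs_developed": [20, 9, 15, 0, 12, 0, 14, 11],
        "eggs_undeveloped": [0, 1, 0, 0, 4, 12, 4, 3],
        "excluded_reason": ["none", "none", "none", "unmated", "none",
                            "zero_development", "none", "none"],
    })


@pytest.fixture
def generated_study():
    from femcost import GeneratorParams, StudyDesign, generate_study
    return generate_study(StudyDesign(), GeneratorParams(seed=7))
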