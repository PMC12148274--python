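import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vteppx import Cohort, ProphylaxisParams, SynthConfig, generate_cohort

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def base_params():
    return ProphylaxisParams()


@pytest.fixture
def tiny_cohort():
    """Six hand-built admissions spanning the interesting rule regions."""
    return Cohort(
        pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(6)],
                # low/low, high/low, high/high-favorable, high/high-unfav,
                # low/high, borderline
                "p_vte": [0.004, 0.020, 0.050, 0.012, 0.005, 0.010],
                "p_bleed": [0.002, 0.001, 0.020, 0.050, 0.030, 0.0078],
                "padua_score": pd.array([1, 5, 6, 4, 2, 4], dtype="Int64"),
                "improve_score": pd.array([2, 3, 8, 5, 9, 7], dtype="Int64"),
                "physician_prophylaxis": [True, False, True, True, False, True],
            }
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort small enough for per-test loops."""
    return generate_cohort(SynthConfig(n=3000, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort at the generator defaults."""
    return generate_cohort(SynthConfig(seed=2025))
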