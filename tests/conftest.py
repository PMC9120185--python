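import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from attiso import GeneratorParams, SurveyDataset, generate_dataset, generate_isolation_gradient
from attiso.synthetic_data import default_items

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_survey(codes, country="AA", n_extra=0):
    """Build a SurveyDataset from an (n, 3 + n_extra) array of level codes."""
    items = default_items(n_extra)
    arr = np.asarray(codes, dtype=float)
    cols = {"country": country}
    for j, it in enumerate(items):
        cols[it.item_id] = arr[:, j]
    return SurveyDataset(pd.DataFrame(cols), items)


@pytest.fixture(scope="session")
def structured_data():
    """Strongly structured single-country survey (low item noise)."""
    return generate_dataset(
        GeneratorParams(n_per_country=2000, item_noise_sd=0.3, seed=6)
    )


@pytest.fixture(scope="session")
def gradient_data():
    """20 countries with decoupling linearly spaced over [0, 0.9]."""
    base = GeneratorParams(n_countries=20, n_per_country=1000, seed=7)
    return generate_isolation_gradient(base, list(np.linspace(0.0, 0.9, 20)))


@pytest.fixture(scope="session")
def gradient_d_values():
    return list(np.linspace(0.0, 0.9, 20))
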