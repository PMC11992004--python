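import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dendritemp.core import AsvTable, validate_metadata  # noqa: E402
from dendritemp.synthetic import SyntheticConfig, generate_dataset  # noqa: E402


@pytest.fixture
def tiny_table() -> AsvTable:
    return AsvTable(pd.DataFrame(
        [[5, 0, 3], [2, 4, 0]],
        index=["s1", "s2"],
        columns=["a1", "a2", "a3"],
    ))


@pytest.fixture
def series_meta() -> pd.DataFrame:
    """One site, one habitat, seven biweekly occasions."""
    rows = [
        {"sample_id": f"s{t}", "site_id": "H1", "habitat": "bacterioplankton",
         "occasion": t, "date": f"2018-07-{t:02d}", "dendritic_distance_km": 0.4}
        for t in range(1, 8)
    ]
    return validate_metadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced pool size for fast end-to-end tests."""
    return SyntheticConfig(n_asv=300, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
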