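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

from chemotaxa import ScenarioConfig, preprocess


@pytest.fixture
def default_config() -> ScenarioConfig:
    return ScenarioConfig(seed=1)


@pytest.fixture
def small_peak_table() -> preprocess.PeakTable:
    """Tiny hand-built peak table: 4 colonies x 5 substances, 2 groups."""
    subs = [preprocess.parse_substance_name(n)
            for n in ["C29", "13-MeC29", "C35:1", "C35:2", "C31"]]
    ab = pd.DataFrame(
        [
            [5.0, 3.0, 1.0, 0.5, 0.5],
            [4.0, 4.0, 1.5, 0.0, 0.5],
            [1.0, 6.0, 2.0, 0.5, 0.5],
            [2.0, 5.0, 2.5, 0.0, 0.5],
        ],
        index=["c1", "c2", "c3", "c4"],
        columns=[s.id for s in subs],
    )
    meta = pd.DataFrame(
        {"chemotype": ["A", "A", "B", "B"], "lon": [0.0, 1.0, 2.0, 3.0],
         "lat": [0.0, 0.5, 1.0, 1.5]},
        index=ab.index,
    )
    return preprocess.PeakTable(ab, subs, meta)
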