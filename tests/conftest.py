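import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from thyroht.cohort import TwoYearDataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_dataset(**columns) -> TwoYearDataset:
    """Assemble a minimal analysis dataset from raw column arrays.

    ``ht_within_2y`` must be among the columns; everything else is passed
    through as predictors.
    """
    frame = pd.DataFrame(columns)
    assert "ht_within_2y" in frame.columns
    frame["ht_within_2y"] = frame["ht_within_2y"].astype(bool)
    return TwoYearDataset(frame=frame, n_excluded=0)
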