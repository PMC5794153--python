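import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_markers():
    """3 individuals x 4 loci with one missing cell."""
    from dominant_sgs import MISSING, MarkerMatrix

    values = np.array(
        [
            [1, 0, 1, 1],
            [0, 1, MISSING, 1],
            [1, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return MarkerMatrix(["a", "b", "c"], ["L1", "L2", "L3", "L4"], values)


@pytest.fixture
def toy_samples():
    from dominant_sgs import SampleTable

    return SampleTable(
        pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "pop": ["X", "X", "Y"],
                "x_m": [0.0, 100.0, 250.0],
                "y_m": [0.0, 0.0, 0.0],
            }
        )
    )
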