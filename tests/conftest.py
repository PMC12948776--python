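import numpy as np
import pandas as pd
import pytest

from pulseval import CohortConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A six-subject synthetic study with the default device roster."""
    return generate_study(CohortConfig(n_subjects=6), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_matched():
    """Hand-sized matched-epoch table with two subjects and one device."""
    return pd.DataFrame(
        {
            "subject_id": ["A", "A", "B", "B"],
            "device_id": "dev",
            "epoch_index": [0, 1, 0, 1],
            "criterion_hr": [100.0, 110.0, 120.0, 130.0],
            "device_hr": [101.0, 113.0, 125.0, 137.0],
            "error": [1.0, 3.0, 5.0, 7.0],
            "abs_error": [1.0, 3.0, 5.0, 7.0],
            "intensity": ["rest", "rest", "rest", "rest"],
            "outlier": False,
        }
    )
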