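import numpy as np
import pandas as pd
import pytest

from neonet.cohort import GROUP_ORDER


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_metadata():
    """Hand-built 12-scan cohort covering all sample-selection branches."""
    rows = [
        # subject, session, ga, pma, sex, dvars, score
        ("s01", "s01_a", 26.5, 32.0, "male", 1.1, 1),
        ("s01", "s01_b", 26.5, 41.0, "male", 1.0, 1),
        ("s02", "s02_a", 30.0, 33.5, "female", 1.2, 2),
        ("s02", "s02_b", 30.0, 40.2, "female", 1.3, 1),
        ("s03", "s03_a", 34.0, 38.0, "male", 1.1, 1),
        ("s04", "s04_a", 38.5, 39.5, "female", 1.2, 1),
        ("s05", "s05_a", 40.1, 41.6, "male", 1.0, 2),
        ("s06", "s06_a", 41.5, 42.5, "female", 1.4, 1),
        ("s07", "s07_a", 42.2, 43.5, "male", 1.2, 1),
        ("s08", "s08_a", 39.0, 40.0, "female", 6.0, 1),   # DVARS outlier
        ("s09", "s09_a", 40.0, 41.0, "male", 1.1, 4),     # radiology exclusion
        ("s10", "s10_a", 36.0, 36.5, "female", 1.0, 1),   # never reaches the window
    ]
    return pd.DataFrame(
        rows,
        columns=["subject_id", "session_id", "ga_birth", "pma_scan", "sex",
                 "mean_dvars", "radiology_score"],
    )


@pytest.fixture
def group_ordinal():
    return {g: i for i, g in enumerate(GROUP_ORDER)}
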