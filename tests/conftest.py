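import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from exoflux import (
    CompoundRecord,
    FeatureTable,
    SpectralLibrary,
    default_adducts,
)


@pytest.fixture
def design_df():
    rows = []
    for org, cond in [("A_host", "start"), ("A_host", "end")]:
        for r in range(1, 5):
            rows.append(
                {
                    "sample_id": f"{org}_{cond}_{r}",
                    "organism": org,
                    "condition": cond,
                    "replicate": r,
                    "polarity": "positive",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def small_table(design_df):
    rng = np.random.default_rng(0)
    features = pd.DataFrame(
        {
            "feature_id": ["f1", "f2", "f3"],
            "mz": [343.1235, 180.0634, 250.1200],
            "rt": [7.4, 3.2, 10.1],
            "polarity": ["positive"] * 3,
        }
    )
    for sid in design_df["sample_id"]:
        features[sid] = rng.uniform(1e4, 1e6, 3)
    return FeatureTable(features=features, design=design_df)


@pytest.fixture
def tiny_library():
    return SpectralLibrary(
        records=[
            CompoundRecord(
                name="trehalose",
                neutral_mass=342.1162,
                adducts=default_adducts(342.1162),
                reference_rt=7.4,
                msms=[(85.0284, 0.6), (127.0390, 1.0), (163.0601, 0.4)],
            ),
            CompoundRecord(
                name="glucose",
                neutral_mass=180.0634,
                adducts=default_adducts(180.0634),
                reference_rt=6.1,
                msms=[],
            ),
        ]
    )
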