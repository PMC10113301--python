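import numpy as np
import pandas as pd
import pytest

from dielniche import datasets


@pytest.fixture(scope="session")
def visit_matrix() -> pd.DataFrame:
    return datasets.load_visit_matrix()


@pytest.fixture(scope="session")
def floral_table() -> pd.DataFrame:
    return datasets.load_floral_table()


def make_events(rows):
    """Visit-event frame from (camera, pollinator, plant, seconds-offset, legit)."""
    base = pd.Timestamp("2019-01-05 06:00:00")
    return pd.DataFrame(
        [
            {
                "camera_id": cam,
                "pollinator": pol,
                "plant": plant,
                "timestamp": base + pd.Timedelta(seconds=s),
                "legitimate": legit,
            }
            for cam, pol, plant, s, legit in rows
        ]
    )


@pytest.fixture()
def events_factory():
    return make_events
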