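import datetime as dt

import numpy as np
import pandas as pd
import pytest

from driftshift.simulate import SimConfig, gen_flyways


@pytest.fixture(scope="session")
def flyways():
    return gen_flyways()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Two years, three species (one per guild), small cells — fast everywhere."""
    return SimConfig(seed=11, years=(2020, 2021), species=("MALL", "SNGO", "NSHO"),
                     observers_per_cell=8)


def make_obs(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical observation table from sparse row dicts."""
    defaults = {
        "checklist_id": None, "group_id": pd.NA, "species": "MALL", "count": 5,
        "presence_only": False, "lat": 35.0, "lon": -90.0,
        "date": dt.date(2021, 1, 15), "protocol": "stationary",
        "travel_km": np.nan, "duration_h": 1.0, "n_observers": 2, "complete": True,
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d["checklist_id"] = f"S{i + 1:08d}"
        d.update(r)
        out.append(d)
    df = pd.DataFrame(out)
    df["count"] = df["count"].astype("Int64")
    return df
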