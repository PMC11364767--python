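import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from chronospread import SyntheticConfig, generate
from chronospread.activity import CATEGORIES, N_BINS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_posts():
    """A small deterministic synthetic post table shared across tests."""
    cfg = SyntheticConfig(n_users=30, seed=7,
                          date_span=("2020-02-01", "2020-06-01"))
    users, posts = generate(cfg)
    return users, posts, cfg


def make_posts_frame(rows, tz="Europe/Rome"):
    """Build a post table from (user_id, iso_timestamp, category) rows."""
    frame = pd.DataFrame(rows, columns=["user_id", "timestamp", "category"])
    frame["timestamp"] = pd.to_datetime(frame["timestamp"], utc=True) \
        .dt.tz_convert(tz)
    frame["lat"] = np.nan
    frame["lon"] = np.nan
    return frame


@pytest.fixture
def indicator_curve():
    def make(bin_index, kind="activity"):
        from chronospread import DiurnalCurve
        values = np.zeros(N_BINS)
        values[bin_index] = 1.0
        return DiurnalCurve(values, kind=kind,
                            normalized=(kind == "activity"))
    return make
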