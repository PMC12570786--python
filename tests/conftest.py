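import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # ephemeris_oracle importable

from antelopy import features, synthetic


def burst_features_frame(labelled: pd.DataFrame, rate: float = 33.0) -> pd.DataFrame:
    """Feature table from a labelled-burst frame (identity orientation)."""
    rows = []
    for _, r in labelled.iterrows():
        b = features.Burst("T", pd.Timestamp("2021-01-01"), rate, r.burst[0], r.burst[1], r.burst[2])
        d = features.extract_features(b)
        d["label"] = r.label_raw
        d["label_class"] = r.label_class
        rows.append(d)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sim_config() -> synthetic.SimConfig:
    return synthetic.SimConfig(seed=11)


@pytest.fixture(scope="session")
def labelled_feature_table(sim_config) -> pd.DataFrame:
    """300 bursts per dominant analysis class with extracted features."""
    lab = synthetic.generate_labelled_bursts(sim_config, n_per_class=300)
    return burst_features_frame(lab)


def make_burst(x, y, z, rate: float = 33.0) -> features.Burst:
    return features.Burst(
        individual_id="T",
        start_utc=pd.Timestamp("2021-06-01T12:00:00"),
        rate=rate,
        x=np.asarray(x),
        y=np.asarray(y),
        z=np.asarray(z),
    )
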