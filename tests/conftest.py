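import numpy as np
import pandas as pd
import pytest

from mapeval import ProfileTable


@pytest.fixture
def toy_table():
    """Two well-separated replicates of perturbation A plus two controls."""
    meta = pd.DataFrame(
        {"pert": ["A", "A", "control", "control"], "plate": ["p1", "p2", "p1", "p2"]},
        index=pd.Index(["a1", "a2", "c1", "c2"], name="profile"),
    )
    X = np.array([[1.0, 0.05], [0.9, 0.1], [0.05, 1.0], [0.1, 0.9]])
    return ProfileTable(meta, X)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_profile_table(rng, n_rows, n_features=4, n_perts=3, n_plates=2):
    """Random metadata + features for brute-force matching oracles."""
    meta = pd.DataFrame(
        {
            "pert": rng.choice([f"P{i}" for i in range(n_perts)], n_rows),
            "plate": rng.choice([f"pl{i}" for i in range(n_plates)], n_rows),
            "well": rng.choice(["w1", "w2"], n_rows),
        },
        index=pd.Index([f"r{i}" for i in range(n_rows)], name="profile"),
    )
    return ProfileTable(meta, rng.normal(size=(n_rows, n_features)))
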