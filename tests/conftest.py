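import numpy as np
import pandas as pd
import pytest

import surprisalx as sx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_positive_matrix(rng, n_rows, n_cols, low=0.5, high=9.0):
    """Random strictly positive expression-like matrix as a DataFrame."""
    values = rng.uniform(low, high, size=(n_rows, n_cols))
    return pd.DataFrame(
        values,
        index=[f"t{i}" for i in range(n_rows)],
        columns=[f"s{k}" for k in range(n_cols)],
    )


@pytest.fixture
def positive_matrix(rng):
    return random_positive_matrix(rng, 12, 8)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted dataset shared across tests (300 transcripts x 80 samples, K=3)."""
    truth = sx.generate_truth(
        n_transcripts=300, n_samples=80, K=3, amplitude=60.0, activation=0.3, seed=11
    )
    return sx.simulate_dataset(truth, noise_sd=0.1, seed=12)


@pytest.fixture(scope="session")
def small_dec(small_sim):
    logx = sx.log_transform(small_sim.dataset)
    return logx, sx.decompose(logx)


@pytest.fixture
def toy_meta():
    """Hand-written metadata: 6 samples, 3 subjects, 3 pathology groups."""
    return pd.DataFrame(
        {
            "sample_id": ["a", "b", "c", "d", "e", "f"],
            "subject_id": ["p1", "p1", "p2", "p2", "p3", "p3"],
            "region": ["Hi", "CN", "Hi", "Pu", "CN", "Hi"],
            "pathology": [
                "definite", "definite", "non-demented",
                "non-demented", "probable", "possible",
            ],
        }
    ).set_index("sample_id", drop=False)


@pytest.fixture
def toy_barcodes():
    """Six hand-written 2-digit barcodes for the toy metadata samples."""
    return pd.DataFrame(
        {
            "digit_1": [1, 1, 0, 0, 1, -1],
            "digit_2": [0, -1, 0, 0, 0, 1],
        },
        index=pd.Index(["a", "b", "c", "d", "e", "f"], name="sample_id"),
    )
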