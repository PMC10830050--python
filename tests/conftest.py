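import logging

import numpy as np
import pandas as pd
import pytest

from audseg.containers import BlockSpec, ResponseMatrix
from audseg.synth import default_config, generate_population

logging.getLogger("audseg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def medium_population():
    """Default-conditions population reused by read-only tests."""
    cfg = default_config(n_respondents=2500, seed=42)
    return generate_population(cfg)


@pytest.fixture()
def tiny_matrix():
    """A hand-sized ResponseMatrix: 4 respondents, 2 blocks, 5-point scale."""
    blocks = BlockSpec(
        item_block={"q1": "blk_a", "q2": "blk_a", "q3": "blk_b", "q4": "blk_b"},
    )
    responses = pd.DataFrame(
        [[3, 3, 3, 3], [1, 5, 1, 5], [2, 4, 5, 1], [5, 5, 5, 5]],
        index=pd.Index([f"r{i}" for i in range(4)], name="respondent_id"),
        columns=["q1", "q2", "q3", "q4"],
        dtype=float,
    )
    return ResponseMatrix(responses=responses, blocks=blocks, likert_levels=5)


def make_blobs_df(rng, centers, n_per, sd=0.3, prefix="r"):
    """Well-separated Gaussian blobs as a factor-score frame."""
    centers = np.asarray(centers, dtype=float)
    rows = []
    labels = []
    for j, c in enumerate(centers):
        rows.append(c + rng.normal(scale=sd, size=(n_per, len(c))))
        labels += [f"blob_{j}"] * n_per
    X = np.vstack(rows)
    idx = pd.Index([f"{prefix}{i}" for i in range(len(X))])
    F = pd.DataFrame(X, index=idx, columns=[f"f{d}" for d in range(centers.shape[1])])
    return F, pd.Series(labels, index=idx)
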