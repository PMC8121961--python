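import numpy as np
import pandas as pd
import pytest

import slodr


@pytest.fixture
def toy_matrix() -> slodr.ScoreMatrix:
    """Small hand-checkable 5 x 3 score table."""
    frame = pd.DataFrame(
        {
            "m1": [1.0, 2.0, 3.0, 4.0, 5.0],
            "m2": [2.0, 1.0, 4.0, 3.0, 5.0],
            "m3": [1.0, 3.0, 2.0, 5.0, 4.0],
        },
        index=pd.Index(["a", "b", "c", "d", "e"], name="person_id"),
    )
    return slodr.ScoreMatrix(frame)


@pytest.fixture(scope="session")
def sim_null() -> slodr.SimResult:
    """Coupling-free symmetric data: lambda=0.7, sigma0=0.714 => unit variance."""
    cfg = slodr.SimConfig(
        n_persons=5000, n_measures=10, loadings=0.7, noise_scale=0.714,
        coupling=0.0, seed=101,
    )
    return slodr.generate_scores(cfg)


@pytest.fixture(scope="session")
def std_null(sim_null) -> slodr.ScoreMatrix:
    return slodr.standardize(sim_null.scores)
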