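import numpy as np
import pandas as pd
import pytest


def make_rep(counts, ids=None) -> pd.DataFrame:
    """Build a clonotype table from a list of counts."""
    counts = list(counts)
    if ids is None:
        ids = [f"T{i:04d}" for i in range(len(counts))]
    return pd.DataFrame({"clonotype_id": ids, "count": counts})


def random_rep(seed: int, max_clones: int = 200) -> pd.DataFrame:
    """Random repertoire mixing uniform and power-law-ish shapes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_clones))
    if rng.random() < 0.5:
        counts = rng.integers(1, 50, size=n)
    else:
        counts = 1 + rng.geometric(0.05, size=n)
    return make_rep(counts.tolist())


@pytest.fixture
def two_clone_rep() -> pd.DataFrame:
    return make_rep([5, 5], ids=["A", "B"])
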