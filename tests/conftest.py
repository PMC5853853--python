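import numpy as np
import pandas as pd
import pytest

from pamptx.simulate import SimConfig, simulate_expression
from pamptx.tables import DIFF_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across read-only tests."""
    config = SimConfig(n_genes=300, seed=42)
    matrix, truth = simulate_expression(config)
    return config, matrix, truth


def make_diff_frame(rows):
    """Build a differential frame from (gene, s1, s2, v1, v2, lfc, p, q[, status]) tuples."""
    full = [tuple(r) + ("OK",) * (9 - len(r)) for r in rows]
    return pd.DataFrame(full, columns=DIFF_COLUMNS)


@pytest.fixture
def diff_builder():
    return make_diff_frame
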