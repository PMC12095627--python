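import numpy as np
import pandas as pd
import pytest


def make_cells(rows, sample_id="s1"):
    """rows: list of (cell_id, x, y, type_l2)."""
    return pd.DataFrame(
        [(cid, sample_id, x, y, t) for cid, x, y, t in rows],
        columns=["cell_id", "sample_id", "x", "y", "type_l2"],
    )


@pytest.fixture
def four_cell_table():
    """The worked 4-cell instance: one X with two Y neighbours, a distant Z."""
    return make_cells(
        [("A", 0.0, 0.0, "X"), ("B", 10.0, 0.0, "Y"),
         ("D", 5.0, 5.0, "Y"), ("E", 100.0, 100.0, "Z")]
    )


@pytest.fixture
def random_cells():
    """Factory for random cell tables used against brute-force oracles."""

    def _make(n, seed, n_types=4, field=200.0):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, field, size=(n, 2))
        types = rng.choice([f"t{k}" for k in range(n_types)], size=n)
        return make_cells(
            [(f"c{i}", xy[i, 0], xy[i, 1], types[i]) for i in range(n)]
        )

    return _make
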