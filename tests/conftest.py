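import numpy as np
import pandas as pd
import pytest

from scalemice import Dataset
from scalemice.fixtures import toy_schema


@pytest.fixture(scope="session")
def toy():
    return toy_schema()


def make_toy_data(n=150, seed=0, item_type="ordinal"):
    """Complete dataset conforming to the toy schema (p, d1..d3, S, T)."""
    rng = np.random.default_rng(seed)
    cols = {"p": rng.integers(0, 2, n).astype(float)}
    for d in ("d1", "d2", "d3"):
        cols[d] = rng.normal(size=n)
    for it in [f"s{i}" for i in range(1, 8)] + [f"t{i}" for i in range(1, 18)]:
        if item_type == "ordinal":
            cols[it] = rng.integers(1, 6, n).astype(float)
        else:
            cols[it] = rng.normal(3.0, 1.0, size=n)
    return Dataset(pd.DataFrame(cols))


def delete_mcar(data, columns, frac, seed=1):
    """Return a copy with `frac` of each listed column deleted at random."""
    rng = np.random.default_rng(seed)
    out = data.copy()
    for c in columns:
        mask = rng.random(out.n) < frac
        out.values.loc[mask, c] = np.nan
    return out


@pytest.fixture
def toy_data():
    return make_toy_data()
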