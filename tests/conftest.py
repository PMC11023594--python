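import numpy as np
import pytest

from madmix.column_models import ColumnSchema, ColumnSpec
from madmix.io_cli import Table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_table(cat_codes=None, num=None, cat_levels=None, n_rows=None):
    """Assemble a Table directly from arrays (levels named '0', '1', ...)."""
    cols = []
    if num is not None:
        num = np.atleast_2d(np.asarray(num, dtype=float))
        if num.shape[0] == 1 and n_rows not in (None, 1):
            num = num.T
        cols += [ColumnSpec(f"num{i}", "numeric") for i in range(num.shape[1])]
    if cat_codes is not None:
        cat_codes = np.atleast_2d(np.asarray(cat_codes, dtype=np.int64))
        if cat_codes.shape[0] == 1 and n_rows not in (None, 1):
            cat_codes = cat_codes.T
        if cat_levels is None:
            cat_levels = [int(cat_codes[:, j].max()) + 2
                          for j in range(cat_codes.shape[1])]
        cols += [
            ColumnSpec(f"cat{i}", "categorical",
                       levels=[str(v) for v in range(k)])
            for i, k in enumerate(cat_levels)
        ]
    n = (num.shape[0] if num is not None else cat_codes.shape[0])
    if cat_codes is None:
        cat_codes = np.empty((n, 0), dtype=np.int64)
    if num is None:
        num = np.empty((n, 0))
    return Table(ColumnSchema(cols), cat_codes, num)


@pytest.fixture
def random_mixed_table(rng):
    """30 rows, 2 categorical (3- and 4-level) + 2 numeric columns."""
    cat = np.column_stack([
        rng.integers(0, 3, 30),
        rng.integers(0, 4, 30),
    ])
    num = rng.normal(0, 2, (30, 2))
    return build_table(cat_codes=cat, num=num, cat_levels=[3, 4])
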