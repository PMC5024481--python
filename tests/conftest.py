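import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bic2pam import CostTable, NumericMatrix


@pytest.fixture
def worked_db():
    """The three printed transactions used throughout the constraint examples."""
    return {
        "x1": {"a", "b", "c"},
        "x2": {"a", "b", "c", "d"},
        "x3": {"a", "d"},
    }


@pytest.fixture
def worked_costs():
    return CostTable({"a": 0, "b": 1, "c": 2, "d": 3})


@pytest.fixture
def small_matrix():
    """4x4 matrix with one missing cell, handy for preprocessing tests."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [2.0, 3.0, 4.0, 5.0],
        [1.0, np.nan, 3.0, 2.0],
        [5.0, 5.0, 5.0, 5.0],
    ])
    return NumericMatrix(["r1", "r2", "r3", "r4"], ["c1", "c2", "c3", "c4"], values)


def random_itemset_db(rng, n_trans=8, n_items=6):
    """Random raw-item transactional database for oracle comparisons."""
    universe = [chr(ord("a") + k) for k in range(n_items)]
    db = {}
    for t in range(n_trans):
        size = int(rng.integers(1, n_items + 1))
        items = rng.choice(universe, size=size, replace=False)
        db[f"t{t + 1}"] = frozenset(str(i) for i in items)
    return db


def random_sequence_db(rng, n_seq=6, n_cols=5):
    """Random item-indexable sequence database (each column once per row)."""
    cols = [f"y{k + 1}" for k in range(n_cols)]
    db = {}
    for s in range(n_seq):
        size = int(rng.integers(2, n_cols + 1))
        chosen = [str(c) for c in rng.choice(cols, size=size, replace=False)]
        elems = []
        i = 0
        while i < len(chosen):
            width = int(rng.integers(1, min(3, len(chosen) - i) + 1))
            elems.append(tuple(sorted(chosen[i:i + width])))
            i += width
        db[f"s{s + 1}"] = tuple(elems)
    return db
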