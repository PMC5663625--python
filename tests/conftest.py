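import numpy as np
import pandas as pd
import pytest

from redescribe.data_model import (Condition, ConjunctiveQuery, Redescription,
                                   TwoViewDataset)


def make_dataset(view1_cols: dict, view2_cols: dict,
                 labels=None) -> TwoViewDataset:
    """Tiny dataset from plain column dicts; NaN/None marks missing."""
    v1 = pd.DataFrame(view1_cols)
    v2 = pd.DataFrame(view2_cols)
    idx = pd.Index([f"i{k}" for k in range(len(v1))], name="id")
    v1.index = idx
    v2.index = idx
    lab = pd.Series(labels, index=idx) if labels is not None else None
    return TwoViewDataset(v1, v2, labels=lab)


@pytest.fixture
def index_dataset():
    """60 instances; every column in both views equals the instance position.

    Lets tests construct a redescription with any contiguous support
    [lo, hi] by putting an interval condition on one column per view.
    """
    n, k = 60, 6
    idx_vals = np.arange(n, dtype=float)
    v1 = {f"a{j}": idx_vals for j in range(k)}
    v2 = {f"b{j}": idx_vals for j in range(k)}
    return make_dataset(v1, v2)


def interval_red(data: TwoViewDataset, lo: int, hi: int,
                 attr1: str = "a0", attr2: str = "b0") -> Redescription:
    """Redescription whose support is positions lo..hi of an index dataset."""
    q1 = ConjunctiveQuery(1, (Condition(attr1, lo=float(lo), hi=float(hi)),))
    q2 = ConjunctiveQuery(2, (Condition(attr2, lo=float(lo), hi=float(hi)),))
    return Redescription(q1, q2, data)
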