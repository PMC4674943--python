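import numpy as np
import pandas as pd
import pytest

from vargwas.pedigree import Pedigree


@pytest.fixture(scope="session")
def fullsib_pedigree():
    """Two founders, two full-sib offspring, one inbred grandchild."""
    return Pedigree.from_records(
        [("A", "0", "0"), ("B", "0", "0"), ("C", "A", "B"), ("D", "A", "B"), ("E", "C", "D")]
    )


@pytest.fixture(scope="session")
def random_pedigree():
    """A 50-animal, 4-generation random-mating pedigree."""
    rng = np.random.default_rng(42)
    recs = [(f"F{i}", None, None) for i in range(10)]
    pool = [r[0] for r in recs]
    counter = 0
    for _gen in range(4):
        new = []
        for _ in range(10):
            s, d = rng.choice(pool, 2, replace=False)
            counter += 1
            aid = f"G{counter}"
            recs.append((aid, s, d))
            new.append(aid)
        pool = pool[-5:] + new
    return Pedigree.from_records(recs)


@pytest.fixture(scope="session")
def litter_table():
    return pd.DataFrame(
        {
            "sow": ["s1"] * 3 + ["s2"] * 2 + ["s3"] * 3 + ["s4"] * 3,
            "parity": [1, 2, 3, 1, 2, 1, 2, 12, 1, 2, 3],
            "fys": ["f1"] * 11,
            "tnb": [10, 12, 14, 9, 11, 3, 30, 13, 13, 13, 13],
        }
    )
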