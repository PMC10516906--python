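import dendropy
import numpy as np
import pandas as pd
import pytest

from ecoassembly.containers import CountTable


@pytest.fixture
def demo_tree() -> dendropy.Tree:
    """((A:1,B:1):1,C:2); — patristic d(A,B)=2, d(A,C)=d(B,C)=4."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        pd.DataFrame(
            [[5, 3, 2], [1, 6, 3]],
            index=["s1", "s2"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
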