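import numpy as np
import pytest

from paretoselect import CriteriaTable, worked_example


@pytest.fixture
def worked() -> CriteriaTable:
    """Six genes, two criteria; frontier {g1, g5, g6} at W=1000."""
    return worked_example()


def random_table(rng: np.random.Generator, n: int, c: int) -> CriteriaTable:
    """Random criteria table with pairwise-distinct values in every column."""
    values = rng.uniform(0.0, 1.0, size=(n, c))
    return CriteriaTable([f"a{i}" for i in range(n)], values,
                         [f"crit{k}" for k in range(c)])
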