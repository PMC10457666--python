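import logging

import numpy as np
import pytest

from circgcf.data_io import AssociationMatrix, AssociationTable, DiseaseDAG

logging.getLogger("circgcf").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The documented 200 x 50 planted-cluster dataset (seed 17)."""
    from circgcf.synthetic import default_fixture

    return default_fixture()


@pytest.fixture
def toy_assoc():
    """6 circRNAs x 4 diseases with a fixed sparse pattern."""
    rng = np.random.default_rng(0)
    values = (rng.random((6, 4)) < 0.4).astype(int)
    values[0, 0] = 1  # guarantee at least one association
    return AssociationMatrix(
        values,
        {f"c{i}": i for i in range(6)},
        {f"d{j}": j for j in range(4)},
    )


@pytest.fixture
def sibling_dag():
    """Two sibling diseases under a single root."""
    return DiseaseDAG([("A", "root"), ("B", "root")])


@pytest.fixture
def small_table():
    return AssociationTable([("c1", "d1"), ("c1", "d2"), ("c2", "d2")])


def random_bipartite(rng, max_n=12, max_m=8):
    """Random small association matrix with at least one link."""
    n = int(rng.integers(2, max_n))
    m = int(rng.integers(2, max_m))
    values = (rng.random((n, m)) < 0.4).astype(int)
    values[rng.integers(n), rng.integers(m)] = 1
    return AssociationMatrix(
        values,
        {f"c{i}": i for i in range(n)},
        {f"d{j}": j for j in range(m)},
    )
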