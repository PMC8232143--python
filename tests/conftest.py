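import numpy as np
import pytest

from ilsbn.dag_core import DAG
from ilsbn.data_sim import fixture_asia, sample_dataset

ASIA_EDGES = [
    ("A", "T"),
    ("S", "L"),
    ("S", "B"),
    ("T", "E"),
    ("L", "E"),
    ("E", "X"),
    ("E", "D"),
    ("B", "D"),
]


@pytest.fixture(scope="session")
def asia_bn():
    return fixture_asia()


@pytest.fixture()
def asia_dag(asia_bn):
    return asia_bn.dag.copy()


@pytest.fixture(scope="session")
def asia_data_1000(asia_bn):
    """One shared 1000-record sample from the chest-clinic fixture."""
    return sample_dataset(asia_bn, 1000, np.random.default_rng(20260919))


@pytest.fixture()
def chain3():
    return DAG(("A", "B", "C"), [("A", "B"), ("B", "C")])
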