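import numpy as np
import pytest

from orthoscan.db import ProteinDatabase, Record
from orthoscan.orthocall import PipelineConfig


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length):
    from orthoscan.synthgen import random_protein as _rp

    return _rp(rng, length)


@pytest.fixture
def duplicated_db(rng):
    """Two organisms carrying identical copies of the same three proteins."""
    records = []
    for k in range(3):
        seq = random_protein(rng, 120)
        for org in ("orgA", "orgB"):
            records.append(Record(id=f"{org}|p{k}", organism=org, seq=seq))
    return ProteinDatabase(records)


@pytest.fixture
def decoy_db(rng):
    """Unrelated random sequences across four organisms."""
    records = []
    for org in ("orgA", "orgB", "orgC", "orgD"):
        for k in range(5):
            records.append(
                Record(id=f"{org}|d{k}", organism=org, seq=random_protein(rng, 150))
            )
    return ProteinDatabase(records)
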