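import numpy as np
import pytest

from mras import NCRNA, TARGET, SequenceRecord, TripartiteNetwork


@pytest.fixture
def chain_network():
    """Minimal d1-t1-r1 chain plus an extra target/ncRNA with no edges."""
    return TripartiteNetwork(
        ["d1"], ["t1", "t2"], ["r1", "r2"],
        np.array([[1.0, 0.0]]),
        np.array([[1.0, 0.0], [0.0, 0.0]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(rng, m, n, p, density=0.4):
    a_dt = (rng.random((m, n)) < density).astype(float)
    a_tr = (rng.random((n, p)) < density).astype(float)
    return TripartiteNetwork(
        [f"d{i}" for i in range(m)],
        [f"t{i}" for i in range(n)],
        [f"r{i}" for i in range(p)],
        a_dt,
        a_tr,
    )


def make_records(seqs, entity_class=NCRNA, prefix="s"):
    return [SequenceRecord(f"{prefix}{i}", s, entity_class) for i, s in enumerate(seqs)]
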