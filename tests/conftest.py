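import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fragmap as fm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: phred high enough that x = 1 - 10^(-q/10) rounds to exactly 1.0 in float64,
#: so scores are exact integers (match 5 / mismatch -4)
Q_EXACT = 600


def make_read(seq, q=Q_EXACT, rid="r", match=5.0, mismatch=-4.0):
    return fm.ReadProfile(rid, seq, np.full(len(seq), q, dtype=np.int64), match, mismatch)


@pytest.fixture
def mk_read():
    return make_read


@pytest.fixture
def toy_ref():
    # 12 bp toy genome that partitions into four fragments of three
    return fm.ReferenceIndex("g", "ACCGTAGGACCA", 3)


def random_ref(rng, min_len=30, max_len=200, name="g"):
    length = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    F = int(rng.integers(4, 33))
    return fm.ReferenceIndex(name, seq, F)


def random_read(rng, min_len=1, max_len=30, rid="r"):
    length = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    quals = rng.integers(0, 41, size=length)
    return fm.ReadProfile(rid, seq, quals)
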