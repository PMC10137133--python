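import numpy as np
import pytest

from nccborrow import AnalysisRecord, Origin


def rec(rid, group, entry, exit_, event, origin=None):
    """Shorthand AnalysisRecord constructor for hand-built fixtures."""
    if origin is None:
        origin = Origin.TREATMENT if group == 1 else Origin.CC
    return AnalysisRecord(str(rid), group, float(entry), float(exit_), bool(event), origin)


@pytest.fixture
def km_records():
    """Three-record delayed-entry fixture: S(2)=2/3, S(3)=1/3 by hand."""
    return [
        rec("r1", 0, 0.0, 2.0, True),
        rec("r2", 0, 1.0, 3.0, True),
        rec("r3", 0, 0.0, 4.0, False),
    ]


@pytest.fixture
def cox4():
    """Four-record Cox fixture; score equation reduces to u^2 - u - 4 = 0."""
    return [
        rec("a", 1, 0.0, 1.0, True),
        rec("b", 0, 0.0, 2.0, True),
        rec("c", 1, 0.0, 3.0, True),
        rec("d", 0, 0.0, 4.0, True),
    ]


@pytest.fixture
def cox4_delayed(cox4):
    """Same but record b enters at 1.5; score equation 2u^3 - 7u - 4 = 0."""
    out = list(cox4)
    out[1] = rec("b", 0, 1.5, 2.0, True)
    return out


@pytest.fixture
def record_factory():
    return rec


@pytest.fixture
def random_instance():
    """Factory for small random counting-process instances (tie-free a.s.)."""

    def make(rng: np.random.Generator, n_max: int = 10):
        while True:
            n = int(rng.integers(4, n_max + 1))
            entry = np.where(rng.random(n) < 0.5, 0.0, rng.uniform(0.0, 2.0, n))
            exit_ = entry + rng.uniform(0.1, 5.0, n)
            event = rng.random(n) < 0.7
            x = (rng.random(n) < 0.5).astype(int)
            if event.sum() == 0 or len(set(x)) < 2:
                continue
            return [
                rec(f"s{i}", int(x[i]), entry[i], exit_[i], bool(event[i]))
                for i in range(n)
            ]

    return make
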