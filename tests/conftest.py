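import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rareset as rs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def f1():
    """Hand-traceable 3-accession example: R = (1/3, 1/9, 2/9), core [A, C]."""
    return rs.make_fixture("F1")


@pytest.fixture(scope="session")
def f2():
    return rs.make_fixture("F2")


@pytest.fixture
def random_accession_matrix():
    """Factory for seeded random z matrices."""

    def make(seed: int, n: int = 10, m: int = 12, B: int = 3) -> rs.AccessionMatrix:
        rng = np.random.default_rng(seed)
        z = rng.integers(0, B + 1, size=(n, m))
        # keep every accession non-empty
        empty = z.sum(axis=1) == 0
        z[empty, 0] = 1
        data = pd.DataFrame(
            z,
            index=pd.Index([f"A{i:03d}" for i in range(n)], name="accession"),
            columns=[f"M{j:02d}_a" for j in range(m)],
        )
        return rs.AccessionMatrix(data=data, bulks_per_accession=B)

    return make
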