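import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from mimicbench.baseline import BaselineSpec, generate_baseline
from mimicbench.containers import CountMatrix
from mimicbench.io_store import filter_features


@pytest.fixture(scope="session")
def baseline_cm():
    """Default filtered synthetic baseline (shared, read-only)."""
    return filter_features(generate_baseline(BaselineSpec(seed=1)))


@pytest.fixture()
def small_cm():
    """Tiny hand-built count matrix (4 features x 6 samples)."""
    counts = np.array(
        [
            [10, 0, 3, 7, 0, 2],
            [0, 0, 0, 1, 0, 0],
            [5, 5, 5, 5, 5, 5],
            [100, 20, 0, 0, 30, 1],
        ]
    )
    return CountMatrix(counts, ["fA", "fB", "fC", "fD"], [f"s{i}" for i in range(6)])
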