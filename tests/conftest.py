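import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bpomics import CountMatrix, LFQMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> CountMatrix:
    """Deterministic 6-gene, 2x3-sample count matrix."""
    rng = np.random.default_rng(1234)
    counts = pd.DataFrame(
        rng.poisson(50, size=(6, 6)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    return CountMatrix(counts=counts, groups=groups)


@pytest.fixture
def small_lfq() -> LFQMatrix:
    """8-protein, 2x4-sample LFQ matrix with a mixed missingness pattern."""
    rng = np.random.default_rng(99)
    vals = rng.normal(20, 2, size=(8, 8))
    vals[0, :3] = np.nan  # group A: 1 observed -> tier 1
    vals[1, 4:] = np.nan  # group B: 0 observed -> tier 1
    vals[2, 0] = np.nan  # group A: 3 observed -> tier 2
    vals[3, [0, 5]] = np.nan  # one missing in each group -> tier 2
    df = pd.DataFrame(
        vals, index=[f"p{i}" for i in range(8)], columns=[f"s{i}" for i in range(8)]
    )
    groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
    return LFQMatrix.from_intensities(df, groups)
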