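import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mhgpipe.containers import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, groups=None, genes=None, probe_ids=None, sample_ids=None):
    """Build a small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"P{i}" for i in range(1, n_probes + 1)]
    sample_ids = sample_ids or [f"S{j}" for j in range(1, n_samples + 1)]
    if groups is None:
        half = n_samples // 2
        groups = ["control"] * half + ["treated"] * (n_samples - half)
    genes = genes or [f"G{i}" for i in range(1, n_probes + 1)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        genes=pd.Series(genes, index=probe_ids),
        groups=pd.Series(list(groups), index=sample_ids),
    )


@pytest.fixture
def small_matrix():
    """4 probes x 4 samples, two groups, no ties."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(8, 1, size=(4, 4)))


@pytest.fixture
def random_matrix():
    """50 probes x 6 samples of continuous (tie-free) intensities."""
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(8, 1.5, size=(50, 6)),
                       groups=["control"] * 3 + ["treated"] * 3)
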