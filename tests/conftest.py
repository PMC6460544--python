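import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from testeval.dta_core import AccuracyRecord, ThresholdDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rng, k=8, n1=120, n0=150, mu=(1.4, 2.2), sd=(0.4, 0.4), threshold=2.0):
    """Heterogeneous single-threshold studies with binomial-free rounding."""
    from scipy.special import expit

    recs = []
    for i in range(k):
        lse = rng.normal(mu[0], sd[0])
        lsp = rng.normal(mu[1], sd[1])
        tp = int(np.clip(round(expit(lse) * n1), 1, n1 - 1))
        tn = int(np.clip(round(expit(lsp) * n0), 1, n0 - 1))
        recs.append(AccuracyRecord(f"s{i}", threshold, tp, n0 - tn, n1 - tp, tn))
    return recs


@pytest.fixture
def hetero_records(rng):
    return make_records(rng)


@pytest.fixture
def hetero_dataset(hetero_records):
    return ThresholdDataset(hetero_records)
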