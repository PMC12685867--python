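import numpy as np
import pytest

from bacpred import FeatureMatrix, FeatureSchema, full_feature_names

ALL_NAMES = full_feature_names()


def make_matrix(values, labels=None, names=None, ids=None):
    """FeatureMatrix helper: columns named from the real vocabulary."""
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    if names is None:
        names = ALL_NAMES[:m]
    if ids is None:
        ids = tuple(f"s{i}" for i in range(values.shape[0]))
    return FeatureMatrix(ids=tuple(ids), values=values,
                         schema=FeatureSchema(tuple(names)), labels=labels)


@pytest.fixture
def planted_matrix():
    """Binary-labeled matrix: first feature copies the label (plus tiny
    jitter so it is continuous), remaining 50 features are N(0,1) noise."""
    def _make(n=60, n_noise=50, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        signal = y + rng.normal(0, 0.05, size=n)
        noise = rng.normal(size=(n, n_noise))
        return make_matrix(np.column_stack([signal, noise]), labels=y)
    return _make
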