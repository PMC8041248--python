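import numpy as np
import pytest

from urimet.io import FeatureRecord, FeatureTable, InjectionRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_table(intensities, klasses, batch_ids=None, feature_ids=None, orders=None):
    """Small FeatureTable from a matrix and per-injection class labels."""
    intensities = np.asarray(intensities, dtype=float)
    n_feat, n_inj = intensities.shape
    assert len(klasses) == n_inj
    batch_ids = batch_ids or ["B1"] * n_inj
    feature_ids = feature_ids or [f"F{i + 1}" for i in range(n_feat)]
    if orders is None:
        counters = {}
        orders = []
        for b in batch_ids:
            counters[b] = counters.get(b, 0) + 1
            orders.append(counters[b])
    features = [FeatureRecord(fid, mz=100.0 + i, rt=1.0 + 0.1 * i) for i, fid in enumerate(feature_ids)]
    injections = [
        InjectionRecord(f"{b}_{o:03d}", order=o, batch_id=b, klass=k)
        for o, b, k in zip(orders, batch_ids, klasses)
    ]
    return FeatureTable.from_records(features, injections, intensities)


@pytest.fixture
def table_factory():
    return make_table
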