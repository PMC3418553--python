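import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirpair.matrix import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, n_pairs=None, feature_ids=None, flags=None):
    """ExpressionMatrix from a 2-D array; columns alternate tumor/normal."""
    values = np.asarray(values, dtype=float)
    n_feat, n_s = values.shape
    assert n_s % 2 == 0
    n_pairs = n_pairs or n_s // 2
    patients = [f"P{p:02d}" for p in range(n_pairs)]
    samples = [f"{p}{s}" for p in patients for s in ("T", "N")]
    meta = pd.DataFrame(
        {"patient_id": np.repeat(patients, 2), "group": ["tumor", "normal"] * n_pairs},
        index=pd.Index(samples, name="sample_id"),
    )
    ids = feature_ids or [f"f{i:03d}" for i in range(n_feat)]
    vals = pd.DataFrame(values, index=pd.Index(ids, name="feature_id"), columns=samples)
    fl = None
    if flags is not None:
        fl = pd.DataFrame(flags, index=vals.index, columns=vals.columns)
    return ExpressionMatrix(values=vals, metadata=meta, flags=fl)


def matrix_from_diffs(diffs, feature_ids=None):
    """Matrix whose tumor-normal paired differences equal ``diffs`` exactly
    (normal columns 0, tumor columns the difference)."""
    diffs = np.asarray(diffs, dtype=float)
    n_feat, n_pairs = diffs.shape
    vals = np.zeros((n_feat, 2 * n_pairs))
    vals[:, 0::2] = diffs
    return make_matrix(vals, n_pairs=n_pairs, feature_ids=feature_ids)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(8, 1, size=(20, 8)))
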