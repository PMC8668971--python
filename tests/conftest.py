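import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def phantom_cohort(tmp_path_factory):
    """Small two-contrast phantom cohort with a strong class effect."""
    from voccspec.phantoms import PhantomConfig, generate_cohort

    out = tmp_path_factory.mktemp("cohort")
    cfg = PhantomConfig(n_codeleted=8, n_nondeleted=4, seed=11)
    manifest = generate_cohort(cfg, out)
    return out, manifest


def separable_table(n=60, seed=0):
    """Linearly separable 2-feature data with 2:1 class imbalance."""
    from voccspec.rusboost import LabeledFeatureTable

    rng = np.random.default_rng(seed)
    n_major, n_minor = 2 * n // 3, n - 2 * n // 3
    X = np.vstack([
        rng.normal([0, 0], 0.5, size=(n_major, 2)),
        rng.normal([4, 4], 0.5, size=(n_minor, 2)),
    ])
    y = np.array(["co-deleted"] * n_major + ["non-deleted"] * n_minor)
    perm = rng.permutation(n)
    return LabeledFeatureTable(X[perm], y[perm])
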