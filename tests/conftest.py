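import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pafentropy as pe

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark_signals():
    """Default 25/25/50 benchmark, cleaned and resampled at 2 Hz."""
    records = pe.make_benchmark(seed=1)
    return [pe.resample_uniform(pe.clean_rr(r)) for r in records]


@pytest.fixture(scope="session")
def paf_vs_normal(benchmark_signals):
    return [s for s in benchmark_signals if s.label in ("PAF", "NORMAL")]


@pytest.fixture(scope="session")
def paf_vs_distant(benchmark_signals):
    return [s for s in benchmark_signals if s.label in ("PAF", "DISTANT")]


@pytest.fixture()
def normal_rr():
    rr, _ = pe.simulate_rr(pe.RRGenConfig(seed=42))
    return rr


def gaussian_features(n_per_class=25, shifted_scales=(), shift=2.0, seed=0):
    """Gaussian feature matrix with a class mean shift on chosen scales."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, 8))
    y = np.concatenate([np.ones(n_per_class), -np.ones(n_per_class)]
                       ).astype(int)
    for j in shifted_scales:
        X[:n_per_class, j - 1] += shift
    return pe.FeatureMatrix(X, y, [f"rec{i}" for i in range(n)],
                            [f"H{j}" for j in range(1, 9)])
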