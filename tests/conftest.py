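import itertools

import numpy as np
import pytest

import cardiocs as cc


@pytest.fixture
def clean_ecg():
    """10 s of noiseless synthetic ECG at 500 Hz with its ground-truth fiducials."""
    return cc.make_ecg(duration=10.0, fs=500.0)


@pytest.fixture
def clean_ppg():
    return cc.make_ppg(duration=10.0, fs=500.0)


@pytest.fixture
def small_gaussian_instance():
    """Seeded 8x12 sensing instance with an exactly 2-sparse target."""

    def make(seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((8, 12))
        a /= np.linalg.norm(a, axis=0)
        support = rng.choice(12, size=2, replace=False)
        theta = np.zeros(12)
        theta[support] = rng.uniform(0.5, 1.5, 2) * rng.choice([-1.0, 1.0], 2)
        return a, theta, a @ theta

    return make


def best_subset_residual(y, a, k):
    """Exhaustive least-squares over all size-k supports; the brute-force oracle."""
    best = np.inf
    for sup in itertools.combinations(range(a.shape[1]), k):
        sub = a[:, sup]
        coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
        best = min(best, float(np.linalg.norm(y - sub @ coef)))
    return best
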