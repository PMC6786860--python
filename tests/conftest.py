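import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def series_expm(A, order=40):
    """Independent matrix-exponential oracle: scaling-and-squaring of the
    plain Taylor series, summed to high order."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    norm = np.abs(A).sum(axis=1).max()
    s = max(0, int(np.ceil(np.log2(max(norm, 1e-300)))) + 1)
    As = A / 2 ** s
    out = np.eye(n)
    term = np.eye(n)
    for k in range(1, order + 1):
        term = term @ As / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def series_affine(A, b, dt, order=40):
    """Oracle for the one-step affine update (M, k) via the augmented system."""
    n = A.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A * dt
    aug[:n, n] = np.asarray(b) * dt
    E = series_expm(aug, order=order)
    return E[:n, :n], E[:n, n]
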