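import numpy as np
import pytest

from mfda_unet import AttentionTriplet, kernel_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_triplet(rng, B=2, N=16, C=8, eps=1e-6):
    """A valid post-kernel-map attention triplet with random features."""
    q = kernel_map(rng.standard_normal((B, N, C)))
    k = kernel_map(rng.standard_normal((B, N, C)))
    v = rng.standard_normal((B, N, C))
    return AttentionTriplet(q, k, v, epsilon=eps)


def finite_diff_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g
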