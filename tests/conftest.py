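import numpy as np
import pytest

from flockdetr.engine.tensor import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def finite_diff_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar-valued f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat_x = x.reshape(-1)
    flat_g = g.reshape(-1)
    for i in range(flat_x.size):
        orig = flat_x[i]
        flat_x[i] = orig + eps
        fp = float(f(x))
        flat_x[i] = orig - eps
        fm = float(f(x))
        flat_x[i] = orig
        flat_g[i] = (fp - fm) / (2 * eps)
    return g


def tensor_of(rng, *shape, scale=1.0, requires_grad=False) -> Tensor:
    return Tensor(rng.standard_normal(shape).astype(np.float32) * scale,
                  requires_grad=requires_grad)
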