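import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(f, x, eps=1e-5):
    """Central-difference gradient of scalar f at float64 array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


@pytest.fixture
def gradcheck():
    """Compare autograd gradient to central differences (float64)."""
    from mrdb.autograd import Tensor

    def check(op, x, rtol=1e-5, atol=1e-6, eps=1e-5):
        x = np.asarray(x, dtype=np.float64)
        t = Tensor(x.copy(), requires_grad=True)
        out = op(t)
        out.sum().backward()
        num = numeric_grad(lambda a: float(op(Tensor(a)).sum().data), x, eps=eps)
        np.testing.assert_allclose(t.grad, num, rtol=rtol, atol=atol)

    return check
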