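"""Gradient and contract checks for the autodiff engine and layers."""

import numpy as np
import pytest

from mrdb.autograd import Tensor, concat, einsum2, linear_scan, stack, where_scalar
from mrdb.autograd.nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    DepthwiseConv2d,
    LayerNorm2d,
    MaxPool2d,
    PointwiseLinear,
)
from mrdb.autograd.optim import Adam

from conftest import numeric_grad


class TestElementwiseGrads:
    @pytest.mark.parametrize("op", [
        lambda t: t * t + 2.0 * t,
        lambda t: (t * 0.3 + 1.5).log(),
        lambda t: t.exp(),
        lambda t: t.sigmoid(),
        lambda t: t.silu(),
        lambda t: t.softplus(),
        lambda t: (t * t + 0.5).sqrt(),
        lambda t: (t + 2.0) ** -0.5,
        lambda t: t.relu(),
        lambda t: 1.0 / (t + 3.0),
        lambda t: (t - 0.2).abs(),
    ], ids=["poly", "log", "exp", "sigmoid", "silu", "softplus", "sqrt",
            "rsqrt", "relu", "recip", "abs"])
    def test_unary(self, op, gradcheck, rng):
        x = rng.normal(size=(3, 4)) + 0.05  # avoid relu/abs kinks at 0
        gradcheck(op, x)

    def test_broadcast_add_mul(self, gradcheck, rng):
        b = rng.normal(size=(1, 4))
        gradcheck(lambda t: (t + Tensor(b)) * Tensor(b * 2.0), rng.normal(size=(3, 4)))

    def test_where_scalar(self, gradcheck, rng):
        x = rng.normal(size=(5, 5))
        mask = x > 0
        gradcheck(lambda t: where_scalar(mask, t * t, t * 3.0), x)

    def test_reductions_and_shapes(self, gradcheck, rng):
        x = rng.normal(size=(2, 3, 4))
        gradcheck(lambda t: t.mean(axis=(0, 2)).sum(), x)
        gradcheck(lambda t: t.transpose(2, 0, 1).reshape(4, 6).sum(axis=1), x)
        gradcheck(lambda t: t.flip(1)[..., :2], x)

    def test_concat_stack(self, gradcheck, rng):
        x = rng.normal(size=(2, 6))
        gradcheck(lambda t: concat([t * 2.0, t], axis=1), x)
        gradcheck(lambda t: stack([t, t * t], axis=0), x)

    def test_matmul(self, rng):
        a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
        (a @ b).sum().backward()
        na = numeric_grad(lambda z: float((Tensor(z) @ b).sum().data), a.data)
        nb = numeric_grad(lambda z: float((a.detach() @ Tensor(z)).sum().data), b.data)
        np.testing.assert_allclose(a.grad, na, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(b.grad, nb, rtol=1e-6, atol=1e-8)

    def test_einsum2(self, rng):
        a = Tensor(rng.normal(size=(2, 3, 5)), requires_grad=True)
        b = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        einsum2("nc,bcl->bnl", b, a).sum().backward()
        na = numeric_grad(lambda z: float(np.einsum("nc,bcl->bnl", b.data, z).sum()), a.data)
        nb = numeric_grad(lambda z: float(np.einsum("nc,bcl->bnl", z, a.data).sum()), b.data)
        np.testing.assert_allclose(a.grad, na, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(b.grad, nb, rtol=1e-6, atol=1e-8)


class TestLinearScan:
    def test_matches_loop(self, rng):
        a = rng.uniform(0, 1, size=(3, 7))
        b = rng.normal(size=(3, 7))
        h = linear_scan(Tensor(a), Tensor(b)).data
        prev = np.zeros(3)
        for t in range(7):
            prev = a[:, t] * prev + b[:, t]
            np.testing.assert_allclose(h[:, t], prev, rtol=1e-12)

    def test_gradients(self, rng):
        a = rng.uniform(0.1, 0.9, size=(2, 5))
        b = rng.normal(size=(2, 5))
        ta = Tensor(a.copy(), requires_grad=True)
        tb = Tensor(b.copy(), requires_grad=True)
        (linear_scan(ta, tb) * Tensor(rng.normal(size=(2, 5)) * 0 + 1)).sum().backward()
        na = numeric_grad(lambda z: float(linear_scan(Tensor(z), Tensor(b)).sum().data), a)
        nb = numeric_grad(lambda z: float(linear_scan(Tensor(a), Tensor(z)).sum().data), b)
        np.testing.assert_allclose(ta.grad, na, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(tb.grad, nb, rtol=1e-6, atol=1e-8)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            linear_scan(Tensor(np.ones((2, 3))), Tensor(np.ones((2, 4))))


def _layer_gradcheck(layer, xshape, rng, rtol=1e-4, atol=1e-6):
    """Numeric gradcheck of a layer wrt input and all parameters (float64)."""
    for p in layer.parameters():
        p.data = p.data.astype(np.float64)
    x = rng.normal(size=xshape)

    def run(xa):
        return float(layer(Tensor(xa)).sum().data)

    t = Tensor(x.copy(), requires_grad=True)
    layer(t).sum().backward()
    np.testing.assert_allclose(t.grad, numeric_grad(run, x), rtol=rtol, atol=atol)
    for name, p in layer.named_parameters():
        base = p.data.copy()

        def run_p(pa, p=p):
            p.data = pa
            val = float(layer(Tensor(x)).sum().data)
            return val

        num = numeric_grad(run_p, base)
        p.data = base
        np.testing.assert_allclose(p.grad, num, rtol=rtol, atol=atol,
                                   err_msg=f"parameter {name}")


class TestLayers:
    def test_conv2d_grad(self, rng):
        _layer_gradcheck(Conv2d(2, 3, 3, stride=2, padding=1, rng=rng), (2, 2, 5, 5), rng)

    def test_conv_transpose_grad(self, rng):
        _layer_gradcheck(ConvTranspose2d(3, 2, 2, stride=2, rng=rng), (2, 3, 4, 4), rng)

    def test_depthwise_grad(self, rng):
        _layer_gradcheck(DepthwiseConv2d(3, 3, rng=rng), (2, 3, 5, 5), rng)

    def test_pointwise_grad(self, rng):
        _layer_gradcheck(PointwiseLinear(3, 4, rng=rng), (2, 3, 3, 3), rng)

    def test_layernorm_grad(self, rng):
        _layer_gradcheck(LayerNorm2d(4), (2, 4, 3, 3), rng, rtol=1e-3, atol=1e-5)

    def test_conv_transpose_doubles_side(self, rng):
        layer = ConvTranspose2d(4, 2, 2, stride=2, rng=rng)
        y = layer(Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32)))
        assert y.shape == (1, 2, 16, 16)

    def test_conv_matches_scipy(self, rng):
        from scipy.signal import correlate2d
        conv = Conv2d(1, 1, 3, padding=1, bias=False, rng=rng)
        x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
        y = conv(Tensor(x)).data[0, 0]
        ref = correlate2d(x[0, 0], conv.weight.data[0, 0], mode="same")
        np.testing.assert_allclose(y, ref, rtol=1e-4, atol=1e-5)

    def test_maxpool(self, rng):
        pool = MaxPool2d(2, stride=2)
        x = Tensor(rng.normal(size=(1, 1, 4, 4)).astype(np.float64), requires_grad=True)
        y = pool(x)
        assert y.shape == (1, 1, 2, 2)
        view = x.data.reshape(2, 2, 2, 2).transpose(0, 2, 1, 3)
        np.testing.assert_allclose(y.data[0, 0], view.reshape(2, 2, 4).max(-1))
        y.sum().backward()
        assert x.grad.sum() == pytest.approx(4.0)  # one winner per window

    def test_batchnorm_train_eval(self, rng):
        bn = BatchNorm2d(3)
        x = Tensor(rng.normal(2.0, 3.0, size=(4, 3, 5, 5)).astype(np.float32))
        y = bn(x)
        np.testing.assert_allclose(y.data.mean(axis=(0, 2, 3)), 0.0, atol=1e-5)
        np.testing.assert_allclose(y.data.std(axis=(0, 2, 3)), 1.0, atol=1e-3)
        bn.eval()
        y2 = bn(x)
        assert not np.allclose(y2.data, y.data)  # running stats, not batch stats

    def test_state_dict_roundtrip(self, rng):
        layer = Conv2d(2, 2, 3, rng=rng)
        state = {k: v.copy() for k, v in layer.state_dict().items()}
        layer.weight.data += 1.0
        layer.load_state_dict(state)
        np.testing.assert_array_equal(layer.weight.data, state["weight"])


class TestAdam:
    def test_quadratic_convergence(self):
        from mrdb.autograd.nn import Parameter
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2
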