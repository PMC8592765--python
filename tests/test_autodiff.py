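"""Numerical gradient checks and contracts for the NumPy autodiff engine.

Every hand-written backward pass is verified against central finite
differences in float64 on small tensors.
"""

import numpy as np
import pytest

from dermseg import nn
from dermseg.nn import functional as F
from dermseg.nn.tensor import Tensor


def numerical_grad(f, arr, eps=1e-5):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        lp = f()
        arr[idx] = orig - eps
        lm = f()
        arr[idx] = orig
        g[idx] = (lp - lm) / (2 * eps)
    return g


def check_op(op, shapes, rng, **kwargs):
    """Assert analytic == numerical gradients for every float input of `op`."""
    arrays = [rng.normal(0, 1, s) for s in shapes]

    def run():
        tensors = [Tensor(a, requires_grad=True) for a in arrays]
        out = op(*tensors, **kwargs)
        return (out * out).sum(), tensors

    loss, tensors = run()
    loss.backward()
    for i, (arr, t) in enumerate(zip(arrays, tensors)):
        num = numerical_grad(lambda: run()[0].item(), arr)
        np.testing.assert_allclose(
            t.grad, num, rtol=1e-4, atol=1e-6, err_msg=f"input {i} of {op}"
        )


CONV_CASES = [
    # (x shape, w shape, kwargs) — plain, strided, grouped, pointwise, depthwise
    ((2, 3, 6, 6), (4, 3, 3, 3), dict(stride=1, padding=1)),
    ((1, 3, 8, 8), (4, 3, 3, 3), dict(stride=2, padding=1)),
    ((2, 4, 6, 6), (6, 2, 3, 3), dict(stride=1, padding=1, groups=2)),
    ((2, 5, 4, 4), (3, 5, 1, 1), dict(stride=1)),
    ((2, 5, 6, 6), (3, 5, 1, 1), dict(stride=2)),
    ((2, 4, 6, 6), (4, 1, 3, 3), dict(stride=1, padding=1, groups=4)),
    ((1, 3, 9, 9), (3, 1, 5, 5), dict(stride=2, padding=2, groups=3)),
]


@pytest.mark.parametrize("xs,ws,kw", CONV_CASES)
def test_conv2d_gradients(xs, ws, kw, rng):
    xa, wa = rng.normal(0, 1, xs), rng.normal(0, 1, ws)
    ba = rng.normal(0, 1, ws[0])

    def run():
        xt = Tensor(xa, requires_grad=True)
        wt = Tensor(wa, requires_grad=True)
        bt = Tensor(ba, requires_grad=True)
        out = F.conv2d(xt, wt, bt, **kw)
        return (out * out).sum(), (xt, wt, bt)

    loss, tensors = run()
    loss.backward()
    for arr, t in zip((xa, wa, ba), tensors):
        num = numerical_grad(lambda: run()[0].item(), arr)
        np.testing.assert_allclose(t.grad, num, rtol=1e-4, atol=1e-6)


def test_conv_transpose_gradients(rng):
    check_op(F.conv_transpose2x, [(2, 3, 4, 4), (3, 5, 2, 2)], rng)


def test_conv_transpose_doubles_resolution(rng):
    x = Tensor(rng.normal(0, 1, (1, 3, 5, 7)))
    w = Tensor(rng.normal(0, 1, (3, 2, 2, 2)))
    assert F.conv_transpose2x(x, w).shape == (1, 2, 10, 14)


@pytest.mark.parametrize(
    "op", [F.relu, F.gelu, F.swish, F.mish, lambda t: t.sigmoid()]
)
def test_pointwise_activation_gradients(op, rng):
    check_op(op, [(3, 4)], rng)


def test_prelu_gradients(rng):
    xa = rng.normal(0, 1, (2, 3, 4, 4))
    sa = np.array([0.3])

    def run():
        xt = Tensor(xa, requires_grad=True)
        st = Tensor(sa, requires_grad=True)
        out = F.prelu(xt, st)
        return (out * out).sum(), (xt, st)

    loss, (xt, st) = run()
    loss.backward()
    np.testing.assert_allclose(
        xt.grad, numerical_grad(lambda: run()[0].item(), xa), rtol=1e-4, atol=1e-6
    )
    np.testing.assert_allclose(
        st.grad, numerical_grad(lambda: run()[0].item(), sa), rtol=1e-4, atol=1e-6
    )


def test_pool_and_upsample_gradients(rng):
    check_op(F.max_pool2x, [(2, 3, 4, 4)], rng)
    check_op(F.global_avg_pool, [(2, 3, 4, 4)], rng)
    check_op(F.upsample_bilinear2x, [(2, 3, 4, 4)], rng)


def test_concat_gradients(rng):
    a, b = rng.normal(0, 1, (1, 2, 3, 3)), rng.normal(0, 1, (1, 4, 3, 3))

    def run():
        ta, tb = Tensor(a, requires_grad=True), Tensor(b, requires_grad=True)
        out = F.concat_channels([ta, tb])
        return (out * out).sum(), (ta, tb)

    loss, (ta, tb) = run()
    loss.backward()
    np.testing.assert_allclose(
        ta.grad, numerical_grad(lambda: run()[0].item(), a), rtol=1e-4, atol=1e-6
    )
    np.testing.assert_allclose(
        tb.grad, numerical_grad(lambda: run()[0].item(), b), rtol=1e-4, atol=1e-6
    )


def test_batch_norm_gradients_training_mode(rng):
    xa = rng.normal(0, 1, (3, 2, 4, 4))
    ga, ba = rng.normal(1, 0.1, 2), rng.normal(0, 0.1, 2)

    def run():
        xt = Tensor(xa, requires_grad=True)
        gt = Tensor(ga, requires_grad=True)
        bt = Tensor(ba, requires_grad=True)
        out = F.batch_norm2d(
            xt, gt, bt, np.zeros(2), np.ones(2), training=True
        )
        return (out * out * out).sum(), (xt, gt, bt)

    loss, tensors = run()
    loss.backward()
    for arr, t in zip((xa, ga, ba), tensors):
        np.testing.assert_allclose(
            t.grad,
            numerical_grad(lambda: run()[0].item(), arr),
            rtol=1e-3,
            atol=1e-6,
        )


def test_batch_norm_eval_uses_running_stats(rng):
    bn = nn.BatchNorm2d(3)
    x = Tensor(rng.normal(2.0, 3.0, (4, 3, 5, 5)).astype(np.float32))
    bn.train()
    bn(x)  # updates running stats
    bn.eval()
    y1, y2 = bn(x), bn(x)
    np.testing.assert_array_equal(y1.data, y2.data)
    # normalising a fresh draw with running stats must not depend on that draw
    z = Tensor(rng.normal(0, 1, (1, 3, 5, 5)).astype(np.float32))
    mean_before = bn.running_mean.copy()
    bn(z)
    np.testing.assert_array_equal(bn.running_mean, mean_before)


def test_max_pool_forward_values():
    x = Tensor(np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4))
    out = F.max_pool2x(x)
    np.testing.assert_array_equal(out.data[0, 0], [[5, 7], [13, 15]])


def test_dropout_inert_in_eval_and_scales_in_train(rng):
    d = nn.Dropout2d(0.5)
    d.rng = np.random.default_rng(0)
    x = Tensor(np.ones((8, 16, 2, 2), np.float32))
    d.eval()
    np.testing.assert_array_equal(d(x).data, x.data)
    d.train()
    out = d(x).data
    assert set(np.unique(out)) <= {0.0, 2.0}  # zeroed or rescaled by 1/(1-p)


def test_adam_minimises_quadratic():
    p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = nn.Adam([p], lr=0.1)
    for _ in range(400):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_backward_accumulates_through_reused_tensor(rng):
    x = Tensor(np.array([2.0]), requires_grad=True)
    y = x * x + x * 3.0  # x reused: dy/dx = 2x + 3 = 7
    y.sum().backward()
    np.testing.assert_allclose(x.grad, [7.0])
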