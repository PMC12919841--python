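"""Oracle and gradient checks for the reverse-mode tensor engine.

Forward passes are compared against scipy reference implementations;
gradients of every differentiable primitive are compared against central
finite differences in float64.
"""

import numpy as np
import pytest
from scipy import signal

from cogattn._tensor import (Tensor, batch_norm2d, conv2d, cross_entropy,
                             maxpool2d, no_grad)
from conftest import check_grad

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# forward oracles
# ---------------------------------------------------------------------------

def _ref_conv2d(x, w, b, stride=1, padding=0, dilation=1):
    """Multi-channel cross-correlation via scipy.signal.correlate2d."""
    n, cin, h, wid = x.shape
    cout, _, kh, kw = w.shape
    wd = np.zeros((cout, cin, dilation * (kh - 1) + 1, dilation * (kw - 1) + 1))
    wd[:, :, ::dilation, ::dilation] = w
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (xp.shape[2] - wd.shape[2]) // stride + 1
    wo = (xp.shape[3] - wd.shape[3]) // stride + 1
    out = np.zeros((n, cout, ho, wo))
    for i in range(n):
        for o in range(cout):
            acc = np.zeros((xp.shape[2] - wd.shape[2] + 1,
                            xp.shape[3] - wd.shape[3] + 1))
            for c in range(cin):
                acc += signal.correlate2d(xp[i, c], wd[o, c], mode="valid")
            out[i, o] = acc[::stride, ::stride] + (b[o] if b is not None else 0.0)
    return out[:, :, :ho, :wo]


@pytest.mark.parametrize("stride,padding,dilation", [
    (1, 0, 1), (1, 1, 1), (2, 1, 1), (1, 2, 2), (2, 3, 2), (1, 6, 2),
])
def test_conv2d_matches_scipy_correlate(stride, padding, dilation):
    x = RNG.normal(size=(2, 3, 9, 8))
    w = RNG.normal(size=(4, 3, 3, 3))
    b = RNG.normal(size=4)
    with no_grad():
        got = conv2d(Tensor(x), Tensor(w), Tensor(b),
                     stride=stride, padding=padding, dilation=dilation).data
    want = _ref_conv2d(x, w, b, stride, padding, dilation)
    assert got.shape == want.shape
    np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-10)


def test_depthwise_conv_matches_grouped_reference():
    c = 5
    x = RNG.normal(size=(2, c, 7, 7))
    w = RNG.normal(size=(c, 1, 3, 3))
    b = RNG.normal(size=c)
    with no_grad():
        got = conv2d(Tensor(x), Tensor(w), Tensor(b),
                     stride=1, padding=1, groups=c).data
    for ch in range(c):
        want = _ref_conv2d(x[:, ch:ch + 1], w[ch:ch + 1], b[ch:ch + 1],
                           stride=1, padding=1)
        np.testing.assert_allclose(got[:, ch:ch + 1], want, atol=1e-10)


def test_maxpool_forward_matches_blockwise_max():
    x = RNG.normal(size=(2, 3, 8, 8))
    with no_grad():
        got = maxpool2d(Tensor(x), 2, 2).data
    want = x.reshape(2, 3, 4, 2, 4, 2).max(axis=(3, 5))
    np.testing.assert_allclose(got, want)


def test_batch_norm_eval_uses_running_statistics():
    x = RNG.normal(size=(2, 3, 4, 4))
    gamma, beta = RNG.normal(size=3), RNG.normal(size=3)
    rm = RNG.normal(size=3).astype(np.float32)
    rv = RNG.uniform(0.5, 2.0, size=3).astype(np.float32)
    with no_grad():
        got = batch_norm2d(Tensor(x), Tensor(gamma), Tensor(beta),
                           rm.copy(), rv.copy(), training=False,
                           momentum=0.1, eps=1e-5).data
    want = ((x - rm[None, :, None, None])
            / np.sqrt(rv[None, :, None, None] + 1e-5)
            * gamma[None, :, None, None] + beta[None, :, None, None])
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-6)


def test_batch_norm_training_zero_mean_unit_variance():
    x = RNG.normal(2.0, 3.0, size=(8, 2, 5, 5))
    rm = np.zeros(2, dtype=np.float32)
    rv = np.ones(2, dtype=np.float32)
    with no_grad():
        got = batch_norm2d(Tensor(x), Tensor(np.ones(2)), Tensor(np.zeros(2)),
                           rm, rv, training=True, momentum=0.1, eps=1e-5).data
    np.testing.assert_allclose(got.mean(axis=(0, 2, 3)), 0.0, atol=1e-8)
    np.testing.assert_allclose(got.std(axis=(0, 2, 3)), 1.0, atol=1e-4)
    # running stats moved toward the batch statistics
    np.testing.assert_allclose(rm, 0.1 * x.mean(axis=(0, 2, 3)), rtol=1e-5)


def test_cross_entropy_matches_log_softmax():
    logits = RNG.normal(size=(6, 4))
    labels = RNG.integers(0, 4, size=6)
    with no_grad():
        got = cross_entropy(Tensor(logits), labels).item()
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    want = -logp[np.arange(6), labels].mean()
    assert abs(got - want) < 1e-10


def test_cross_entropy_stable_under_large_logits():
    logits = np.array([[1000.0, 0.0], [0.0, 1000.0]])
    with no_grad():
        loss = cross_entropy(Tensor(logits), np.array([0, 1])).item()
    assert np.isfinite(loss) and loss < 1e-6


# ---------------------------------------------------------------------------
# gradient checks (float64, central differences)
# ---------------------------------------------------------------------------

def test_grad_elementwise_chain():
    x0 = RNG.normal(size=(3, 4))
    rel, _, _ = check_grad(lambda t: ((t * 2.0 + 1.0).sigmoid() * t).mean(), x0)
    assert rel < 1e-6


def test_grad_relu_away_from_kink():
    x0 = RNG.normal(size=(3, 4))
    x0[np.abs(x0) < 0.1] += 0.2  # keep clear of the nondifferentiable point
    rel, _, _ = check_grad(lambda t: (t.relu() * t).sum(), x0)
    assert rel < 1e-6


def test_grad_matmul_and_broadcast_add():
    w = RNG.normal(size=(4, 3))
    b = RNG.normal(size=3)
    x0 = RNG.normal(size=(5, 4))
    rel, _, _ = check_grad(lambda t: ((t @ Tensor(w)) + Tensor(b)).sum(), x0)
    assert rel < 1e-6


def test_grad_conv2d_input_weight_bias():
    x0 = RNG.normal(size=(2, 2, 5, 5))
    w0 = RNG.normal(size=(3, 2, 3, 3))
    b0 = RNG.normal(size=3)
    rel, _, _ = check_grad(
        lambda t: conv2d(t, Tensor(w0), Tensor(b0), padding=1).sum(), x0)
    assert rel < 1e-6
    rel, _, _ = check_grad(
        lambda t: conv2d(Tensor(x0), t, Tensor(b0), padding=1).sum(), w0)
    assert rel < 1e-6
    rel, _, _ = check_grad(
        lambda t: conv2d(Tensor(x0), Tensor(w0), t, padding=1).sum(), b0)
    assert rel < 1e-6


def test_grad_dilated_and_strided_conv():
    x0 = RNG.normal(size=(1, 2, 8, 8))
    w0 = RNG.normal(size=(2, 2, 3, 3))
    rel, _, _ = check_grad(
        lambda t: conv2d(t, Tensor(w0), None, stride=2, padding=2,
                         dilation=2).sum(), x0)
    assert rel < 1e-6
    rel, _, _ = check_grad(
        lambda t: conv2d(Tensor(x0), t, None, stride=2, padding=2,
                         dilation=2).sum(), w0)
    assert rel < 1e-6


def test_grad_depthwise_conv():
    x0 = RNG.normal(size=(2, 3, 6, 6))
    w0 = RNG.normal(size=(3, 1, 3, 3))
    rel, _, _ = check_grad(
        lambda t: conv2d(t, Tensor(w0), None, padding=1, groups=3).sum(), x0)
    assert rel < 1e-6
    rel, _, _ = check_grad(
        lambda t: conv2d(Tensor(x0), t, None, padding=1, groups=3).sum(), w0)
    assert rel < 1e-6


def test_grad_maxpool_routes_to_argmax():
    x0 = RNG.normal(size=(2, 2, 6, 6)) + \
        np.arange(36).reshape(1, 1, 6, 6) * 0.01  # break ties
    rel, _, _ = check_grad(lambda t: (maxpool2d(t, 2, 2) ** 2).sum(), x0)
    assert rel < 1e-6


def test_grad_batch_norm_training_mode():
    x0 = RNG.normal(size=(4, 2, 3, 3))
    g0, b0 = RNG.normal(size=2), RNG.normal(size=2)

    def bn_on(t):
        return batch_norm2d(t, Tensor(g0), Tensor(b0),
                            np.zeros(2, np.float32), np.ones(2, np.float32),
                            training=True, momentum=0.1, eps=1e-5)

    # central differences on BN suffer cancellation at tiny eps, so use a
    # larger step; truncation error is still far below the tolerance
    rel, _, _ = check_grad(lambda t: (bn_on(t) * bn_on(t)).sum(), x0, eps=1e-3)
    assert rel < 1e-5
    rel, _, _ = check_grad(
        lambda t: (batch_norm2d(Tensor(x0), t, Tensor(b0),
                                np.zeros(2, np.float32), np.ones(2, np.float32),
                                True, 0.1, 1e-5) ** 2).sum(), g0, eps=1e-3)
    assert rel < 1e-5


def test_grad_cross_entropy_is_softmax_minus_onehot():
    logits = RNG.normal(size=(5, 3))
    labels = np.array([0, 2, 1, 1, 0])
    t = Tensor(logits.copy(), requires_grad=True)
    cross_entropy(t, labels).backward()
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    onehot = np.eye(3)[labels]
    np.testing.assert_allclose(t.grad, (p - onehot) / 5, atol=1e-10)


def test_grad_reductions_and_max_tie_sharing():
    x0 = RNG.normal(size=(3, 4, 2))
    rel, _, _ = check_grad(lambda t: (t.mean(axis=(1, 2)) ** 2).sum(), x0)
    assert rel < 1e-6
    # max with an exact tie distributes gradient across the tied entries
    x = Tensor(np.array([[1.0, 3.0, 3.0]]), requires_grad=True)
    x.max(axis=1).sum().backward()
    assert x.grad[0, 0] == 0.0
    assert abs(x.grad[0, 1:].sum() - 1.0) < 1e-12


def test_no_grad_builds_no_graph():
    with no_grad():
        t = Tensor(np.ones((2, 2)), requires_grad=True)
        out = (t * 2).sum()
    assert out._backward is None or not out.requires_grad


def test_backward_accumulates_over_reused_node():
    x = Tensor(np.array([2.0]), requires_grad=True)
    y = x * x + x  # dy/dx = 2x + 1 = 5
    y.sum().backward()
    np.testing.assert_allclose(x.grad, [5.0])
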