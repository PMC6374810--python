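"""Gradient and forward correctness of the autodiff engine.

Every op's backward pass is checked against central finite differences in
float64; the convolution forward is additionally checked against a scipy
per-channel correlation oracle.
"""

import numpy as np
import pytest
from scipy.ndimage import correlate

from msdseg import nn
from conftest import finite_difference_grad


def _loss_of(t):
    """Simple weighted-sum scalar readout so gradients are nontrivial."""
    w = np.sin(np.arange(t.data.size)).reshape(t.data.shape)
    return (t.data * w).sum(), w


@pytest.mark.parametrize("n,ci,co,size,kernel", [
    (1, 3, 2, 6, 3),
    (2, 5, 4, 4, 3),
    (1, 4, 3, 5, 1),
])
def test_conv3d_forward_matches_scipy(rng, n, ci, co, size, kernel):
    x = rng.standard_normal((n, ci, size, size, size))
    w = rng.standard_normal((co, ci, kernel, kernel, kernel))
    y = nn.conv3d(nn.Tensor(x), nn.Tensor(w)).data
    ref = np.zeros((n, co, size, size, size))
    for b in range(n):
        for o in range(co):
            for i in range(ci):
                ref[b, o] += correlate(x[b, i], w[o, i], mode="constant")
    np.testing.assert_allclose(y, ref, atol=1e-10)


@pytest.mark.parametrize("op,shapes", [
    ("conv3", ((1, 3, 4, 4, 4), (2, 3, 3, 3, 3))),
    ("conv1", ((1, 3, 4, 4, 4), (2, 3, 1, 1, 1))),
    ("deconv", ((1, 3, 3, 3, 3), (3, 2, 2, 2, 2))),
])
def test_conv_like_gradients_match_finite_differences(rng, op, shapes):
    xs, ws = shapes
    x = nn.Tensor(rng.standard_normal(xs), requires_grad=True)
    w = nn.Tensor(rng.standard_normal(ws), requires_grad=True)
    fn = {"conv3": nn.conv3d, "conv1": nn.conv3d,
          "deconv": nn.conv_transpose3d_s2}[op]

    out = fn(x, w)
    _, wt = _loss_of(out)
    out.grad = wt.copy()
    out._backward(out.grad)

    for t in (x, w):
        num = finite_difference_grad(
            lambda: (fn(nn.Tensor(x.data), nn.Tensor(w.data)).data * wt).sum(),
            t.data)
        np.testing.assert_allclose(t.grad, num, rtol=1e-6, atol=1e-8)


def test_maxpool_gradient_matches_finite_differences(rng):
    x = nn.Tensor(rng.standard_normal((1, 2, 4, 4, 4)), requires_grad=True)
    out = nn.maxpool3d_s2(x)
    _, wt = _loss_of(out)
    out._backward(wt)
    num = finite_difference_grad(
        lambda: (nn.maxpool3d_s2(nn.Tensor(x.data)).data * wt).sum(), x.data)
    np.testing.assert_allclose(x.grad, num, rtol=1e-6, atol=1e-8)


def test_maxpool_rejects_odd_dims(rng):
    with pytest.raises(ValueError, match="even"):
        nn.maxpool3d_s2(nn.Tensor(rng.standard_normal((1, 1, 3, 4, 4))))


def test_batchnorm_gradients_match_finite_differences(rng):
    x = nn.Tensor(rng.standard_normal((2, 3, 3, 4, 4)), requires_grad=True)
    bn = nn.BatchNorm3d(3, dtype=np.float64)
    bn.gamma.data = rng.standard_normal(3)
    bn.beta.data = rng.standard_normal(3)

    def fwd():
        b2 = nn.BatchNorm3d(3, dtype=np.float64)
        b2.gamma.data, b2.beta.data = bn.gamma.data, bn.beta.data
        return b2(nn.Tensor(x.data), train=True).data

    out = bn(x, train=True)
    _, wt = _loss_of(out)
    out._backward(wt)
    for t in (x, bn.gamma, bn.beta):
        num = finite_difference_grad(lambda: (fwd() * wt).sum(), t.data)
        np.testing.assert_allclose(t.grad, num, rtol=1e-5, atol=1e-7)


def test_batchnorm_eval_uses_running_stats(rng):
    bn = nn.BatchNorm3d(2)
    x = nn.Tensor(rng.standard_normal((4, 2, 4, 4, 4)).astype(np.float32))
    for _ in range(50):
        bn(x, train=True)
    y_eval = bn(x, train=False).data
    y_train = bn(x, train=True).data
    np.testing.assert_allclose(y_eval, y_train, atol=1e-2)
    x2 = nn.Tensor(rng.standard_normal((1, 2, 2, 2, 2)).astype(np.float32))
    a = bn(x2, train=False).data
    b = bn(x2, train=False).data
    np.testing.assert_array_equal(a, b)


def test_softmax_cross_entropy_gradient_and_value(rng):
    logits = nn.Tensor(rng.standard_normal((2, 3, 2, 2, 2)), requires_grad=True)
    labels = rng.integers(0, 3, (2, 2, 2, 2))
    loss = nn.softmax_cross_entropy(logits, labels)

    # value: brute-force per-voxel -log softmax
    p = np.exp(logits.data) / np.exp(logits.data).sum(axis=1, keepdims=True)
    ref = 0.0
    cnt = 0
    for idx in np.ndindex(2, 2, 2, 2):
        b, d, h, w = idx
        ref -= np.log(p[b, labels[b, d, h, w], d, h, w])
        cnt += 1
    np.testing.assert_allclose(float(loss.data), ref / cnt, rtol=1e-12)

    loss.backward()
    num = finite_difference_grad(
        lambda: float(nn.softmax_cross_entropy(nn.Tensor(logits.data),
                                               labels).data),
        logits.data)
    np.testing.assert_allclose(logits.grad, num, rtol=1e-5, atol=1e-9)


def test_concat_relu_dropout_bias_backward(rng):
    a = nn.Tensor(rng.standard_normal((1, 2, 2, 2, 2)), requires_grad=True)
    b = nn.Tensor(rng.standard_normal((1, 3, 2, 2, 2)), requires_grad=True)
    bias = nn.Tensor(rng.standard_normal(5), requires_grad=True)
    out = nn.add_channel_bias(nn.relu(nn.concat_channels([a, b])), bias)
    _, wt = _loss_of(out)

    def fwd():
        return (nn.add_channel_bias(
            nn.relu(nn.concat_channels([nn.Tensor(a.data), nn.Tensor(b.data)])),
            nn.Tensor(bias.data)).data * wt).sum()

    out.backward(wt)
    for t in (a, b, bias):
        num = finite_difference_grad(fwd, t.data)
        np.testing.assert_allclose(t.grad, num, rtol=1e-6, atol=1e-9)


def test_dropout_identity_in_eval_and_scales_in_train(rng):
    x = nn.Tensor(np.ones((1, 1, 4, 4, 4)))
    assert nn.dropout(x, 0.5, rng, train=False) is x
    y = nn.dropout(x, 0.5, np.random.default_rng(0), train=True).data
    assert set(np.unique(y)) <= {0.0, 2.0}  # inverted dropout scaling


def test_no_grad_suppresses_graph(rng):
    x = nn.Tensor(rng.standard_normal((1, 2, 4, 4, 4)), requires_grad=True)
    w = nn.Tensor(rng.standard_normal((2, 2, 3, 3, 3)), requires_grad=True)
    with nn.no_grad():
        y = nn.conv3d(x, w)
    assert not y.requires_grad and y._backward is None
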