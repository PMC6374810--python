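"""Minimal reverse-mode autodiff engine for small 3D convolutional networks.

All activations are ``(N, C, D, H, W)`` arrays.  The computation graph is
built dynamically by the functional ops below; calling :meth:`Tensor.backward`
on a scalar loss accumulates gradients into every reachable parameter.

The engine is deliberately small: it supports exactly the ops needed by a
dual-path densely connected segmentation network (stride-1 "same" 3D
convolution, 2x2x2 stride-2 max pooling and transposed convolution, batch
normalization, ReLU, dropout, channel concatenation, softmax and fused
softmax cross-entropy).  Convolutions are evaluated as matrix products
(im2col / shifted-slice contractions) so the heavy lifting is done by BLAS.
Gradient correctness of every op is pinned by finite-difference tests.
"""

from __future__ import annotations

import contextlib
from itertools import product as _iterproduct

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray plus an optional backward closure and parent links."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Reverse-mode sweep from this tensor (seed gradient: ones)."""
        topo = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures as we go


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, copy=True)
    else:
        t.grad += g


def _make(data, parents, backward):
    rg = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not rg:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _pad_spatial(x, pads):
    pd, ph, pw = pads
    if pd == ph == pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))


def _conv3d_forward(x, w, pads):
    """Stride-1 'same' convolution via flat-shift GEMM formulations.

    On the zero-padded grid each kernel offset is a constant flat 1D shift,
    and wrap-around reads land on pad cells that are exactly zero, so shifts
    reduce to contiguous slice copies/additions.  Two GEMM layouts are
    available — contracting over input channels (weights stacked per offset)
    or over channels x offsets (im2col-style columns built by flat shifts) —
    and the one giving the fatter matrix product is chosen per call.
    """
    n, ci = x.shape[:2]
    co = w.shape[0]
    kd, kh, kw = w.shape[2:]
    if (kd, kh, kw) == (1, 1, 1):
        y = np.matmul(w.reshape(co, ci), x.reshape(n, ci, -1))
        return y.reshape(n, co, *x.shape[2:])
    xp = _pad_spatial(x, pads)
    dp, hp, wp = xp.shape[2:]
    p = dp * hp * wp
    xt = np.ascontiguousarray(xp.reshape(n, ci, p).transpose(1, 0, 2)).reshape(ci, n * p)
    offsets = list(_iterproduct(range(kd), range(kh), range(kw)))
    nk = len(offsets)
    deltas = [(a - pads[0]) * hp * wp + (b - pads[1]) * wp + (c - pads[2])
              for a, b, c in offsets]
    d, h, w_ = x.shape[2:]
    score_a = min(nk * co, 64) * min(ci, 256)
    score_b = min(co, 64) * min(nk * ci, 256)
    if score_a >= score_b:
        # contract over ci: t = W(offset,co,ci) @ X, then shifted adds
        wall = np.ascontiguousarray(w.transpose(2, 3, 4, 0, 1)).reshape(nk * co, ci)
        ypad = np.zeros((co, n, p), dtype=x.dtype)
        q = max(1, min(nk, int(128e6 / (co * n * p * x.dtype.itemsize))))
        for s in range(0, nk, q):
            t = np.matmul(wall[s * co:(s + len(offsets[s:s + q])) * co], xt)
            t = t.reshape(-1, co, n, p)
            for i, dlt in enumerate(deltas[s:s + q]):
                if dlt >= 0:
                    ypad[:, :, :p - dlt] += t[i, :, :, dlt:]
                else:
                    ypad[:, :, -dlt:] += t[i, :, :, :p + dlt]
        ypad = ypad.reshape(co, n, dp, hp, wp)
        y = ypad[:, :, pads[0]:pads[0] + d, pads[1]:pads[1] + h, pads[2]:pads[2] + w_]
        return np.ascontiguousarray(y.transpose(1, 0, 2, 3, 4))
    # contract over ci*offsets: build column matrix by flat shifts of X,
    # processed in column blocks to cap the temporary at ~128 MB
    w2 = np.ascontiguousarray(w.transpose(0, 2, 3, 4, 1)).reshape(co, nk * ci)
    npp = n * p
    ypad = np.empty((co, npp), dtype=x.dtype)
    bs = max(4096, int(128e6 / (nk * ci * x.dtype.itemsize)))
    col = np.empty((nk, ci, min(bs, npp)), dtype=x.dtype)
    for c0 in range(0, npp, bs):
        c1 = min(c0 + bs, npp)
        blk = col[:, :, :c1 - c0]
        for i, dlt in enumerate(deltas):
            lo, hi = c0 + dlt, c1 + dlt
            slo, shi = max(lo, 0), min(hi, npp)
            if slo >= shi:
                blk[i] = 0.0
                continue
            if slo > lo:
                blk[i, :, :slo - lo] = 0.0
            if shi < hi:
                blk[i, :, shi - lo:] = 0.0
            blk[i, :, slo - lo:shi - lo] = xt[:, slo:shi]
        ypad[:, c0:c1] = np.matmul(w2, blk.reshape(nk * ci, c1 - c0))
    ypad = ypad.reshape(co, n, dp, hp, wp)
    y = ypad[:, :, pads[0]:pads[0] + d, pads[1]:pads[1] + h, pads[2]:pads[2] + w_]
    return np.ascontiguousarray(y.transpose(1, 0, 2, 3, 4))


def _conv3d_grad_w(x, gy, wshape, pads):
    """Weight gradient via one GEMM against the padded input.

    The output gradient (few channels) is zero-embedded into a grid two
    pads larger; each kernel offset is then a cheap shifted *view* of that
    grid, contracted against the contiguous padded input.
    """
    n, ci = x.shape[:2]
    co = wshape[0]
    kd, kh, kw = wshape[2:]
    d, h, w_ = x.shape[2:]
    if (kd, kh, kw) == (1, 1, 1):
        gw = np.tensordot(gy.reshape(n, co, -1), x.reshape(n, ci, -1),
                          axes=([0, 2], [0, 2]))
        return gw.reshape(wshape)
    pd, ph, pw = pads
    xp = _pad_spatial(x, pads)
    dp, hp, wp = xp.shape[2:]
    p = dp * hp * wp
    xt = np.ascontiguousarray(xp.reshape(n, ci, p).transpose(1, 0, 2)).reshape(ci, n * p)
    # zero-embed gy into the padded grid; each kernel offset is then a flat
    # 1D shift of that grid (wrapped reads hit zero pad cells), so building
    # the stacked left-hand side needs only contiguous copies.
    gyp = np.zeros((co, n, p), dtype=gy.dtype)
    gyp.reshape(co, n, dp, hp, wp)[
        :, :, pads[0]:pads[0] + d, pads[1]:pads[1] + h, pads[2]:pads[2] + w_] = (
        gy.transpose(1, 0, 2, 3, 4))
    gyp = gyp.reshape(co, n * p)
    offsets = list(_iterproduct(range(kd), range(kh), range(kw)))
    q = max(1, min(len(offsets), int(128e6 / (co * n * p * x.dtype.itemsize))))
    gw = np.empty(wshape, dtype=x.dtype)
    gq = np.zeros((q, co, n * p), dtype=x.dtype)
    for s in range(0, len(offsets), q):
        chunk = offsets[s:s + q]
        for i, (a, b, c) in enumerate(chunk):
            dlt = (a - pads[0]) * hp * wp + (b - pads[1]) * wp + (c - pads[2])
            gq[i] = 0.0
            if dlt >= 0:
                gq[i, :, dlt:] = gyp[:, :n * p - dlt]
            else:
                gq[i, :, :n * p + dlt] = gyp[:, -dlt:]
        gall = np.matmul(gq[:len(chunk)].reshape(len(chunk) * co, n * p), xt.T)
        gall = gall.reshape(len(chunk), co, ci)
        for i, (a, b, c) in enumerate(chunk):
            gw[:, :, a, b, c] = gall[i]
    return gw


def _conv3d_grad_x(gy, w, pads):
    # full correlation: convolve gy with the spatially flipped, transposed kernel
    wt = np.ascontiguousarray(w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
    return _conv3d_forward(gy, wt, pads)


def conv3d(x: Tensor, w: Tensor) -> Tensor:
    """Stride-1 'same' 3D convolution (cross-correlation), odd kernel, no bias."""
    kshape = w.data.shape[2:]
    pads = tuple(k // 2 for k in kshape)
    y = _conv3d_forward(x.data, w.data, pads)

    def backward(gy):
        if w.requires_grad:
            _accum(w, _conv3d_grad_w(x.data, gy, w.data.shape, pads))
        if x.requires_grad:
            _accum(x, _conv3d_grad_x(gy, w.data, pads))

    return _make(y, (x, w), backward)


def conv_transpose3d_s2(x: Tensor, w: Tensor) -> Tensor:
    """2x2x2 transposed convolution with stride 2 (exact x2 upsampling).

    ``w`` has shape (C_in, C_out, 2, 2, 2); output spatial dims double.
    """
    n, ci, d, h, w_ = x.data.shape
    co = w.data.shape[1]
    w2 = w.data.reshape(ci, co * 8)
    t = np.matmul(w2.T, x.data.reshape(n, ci, -1))          # (N, Co*8, M)
    y = (t.reshape(n, co, 2, 2, 2, d, h, w_)
          .transpose(0, 1, 5, 2, 6, 3, 7, 4)
          .reshape(n, co, 2 * d, 2 * h, 2 * w_))

    def backward(gy):
        gt = (gy.reshape(n, co, d, 2, h, 2, w_, 2)
                .transpose(0, 1, 3, 5, 7, 2, 4, 6)
                .reshape(n, co * 8, d * h * w_))
        if w.requires_grad:
            gw = np.tensordot(x.data.reshape(n, ci, -1), gt, axes=([0, 2], [0, 2]))
            _accum(w, gw.reshape(w.data.shape))
        if x.requires_grad:
            _accum(x, np.matmul(w2, gt).reshape(x.data.shape))

    return _make(y, (x, w), backward)


def maxpool3d_s2(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool3d_s2 requires even spatial dims, got {(d, h, w)}")
    v = (x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
          .transpose(0, 1, 2, 4, 6, 3, 5, 7)
          .reshape(n, c, d // 2, h // 2, w // 2, 8))
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(gy):
        gz = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
        np.put_along_axis(gz, idx[..., None], gy[..., None], axis=-1)
        gx = (gz.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(n, c, d, h, w))
        _accum(x, gx)

    return _make(y, (x,), backward)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)

    def backward(gy):
        _accum(x, gy * (x.data > 0))

    return _make(y, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate == 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    y = x.data * keep

    def backward(gy):
        _accum(x, gy * keep)

    return _make(y, (x,), backward)


def concat_channels(tensors) -> Tensor:
    tensors = list(tensors)
    if len(tensors) == 1:
        return tensors[0]
    sizes = [t.data.shape[1] for t in tensors]
    y = np.concatenate([t.data for t in tensors], axis=1)

    def backward(gy):
        off = 0
        for t, s in zip(tensors, sizes):
            _accum(t, gy[:, off:off + s])
            off += s

    return _make(y, tuple(tensors), backward)


def add_channel_bias(x: Tensor, b: Tensor) -> Tensor:
    y = x.data + b.data.reshape(1, -1, 1, 1, 1)

    def backward(gy):
        if b.requires_grad:
            _accum(b, gy.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            _accum(x, gy)

    return _make(y, (x, b), backward)


def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(gy):
        dot = (gy * p).sum(axis=1, keepdims=True)
        _accum(x, p * (gy - dot))

    return _make(p, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-voxel cross-entropy (nats) of a softmax over the channel axis.

    ``labels`` is an integer array of shape (N, D, H, W).
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    se = e.sum(axis=1, keepdims=True)
    logp = z - np.log(se)
    n, c = logits.data.shape[:2]
    labels = np.asarray(labels)
    flat = np.take_along_axis(logp, labels[:, None].astype(np.int64), axis=1)
    m = flat.size
    loss = -flat.sum(dtype=np.float64) / m

    def backward(gy):
        p = e / se
        p -= labels[:, None] == np.arange(c).reshape(1, c, 1, 1, 1)
        _accum(logits, (gy * p / m).astype(logits.data.dtype))

    return _make(np.float64(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv3d:
    """Stride-1 'same' convolution layer, bias optional."""

    def __init__(self, in_channels, out_channels, kernel=3, bias=False,
                 dtype=np.float32):
        k = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
        fan_in = in_channels * int(np.prod(k))
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            (np.random.default_rng(0).standard_normal((out_channels, in_channels) + k)
             * scale).astype(dtype),
            requires_grad=True)
        self.bias = (Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
                     if bias else None)

    def __call__(self, x):
        y = conv3d(x, self.weight)
        if self.bias is not None:
            y = add_channel_bias(y, self.bias)
        return y

    def parameters(self):
        yield "weight", self.weight
        if self.bias is not None:
            yield "bias", self.bias


class ConvTranspose3d_s2:
    def __init__(self, in_channels, out_channels, dtype=np.float32):
        scale = np.sqrt(2.0 / (in_channels * 8))
        self.weight = Tensor(
            (np.random.default_rng(0).standard_normal((in_channels, out_channels, 2, 2, 2))
             * scale).astype(dtype),
            requires_grad=True)

    def __call__(self, x):
        return conv_transpose3d_s2(x, self.weight)

    def parameters(self):
        yield "weight", self.weight


class BatchNorm3d:
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        axes = (0, 2, 3, 4)
        if train:
            # numpy's pairwise summation keeps float32 moments accurate here
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(x.data.dtype)
        mean = mean.astype(x.data.dtype)
        sh = (1, -1, 1, 1, 1)
        xhat = (x.data - mean.reshape(sh)) / std.reshape(sh)
        y = self.gamma.data.reshape(sh) * xhat + self.beta.data.reshape(sh)
        gamma, beta = self.gamma, self.beta

        def backward(gy):
            dgamma = (gy * xhat).sum(axis=axes)
            dbeta = gy.sum(axis=axes)
            if gamma.requires_grad:
                _accum(gamma, dgamma)
            if beta.requires_grad:
                _accum(beta, dbeta)
            if x.requires_grad:
                gscale = (gamma.data / std).reshape(sh)
                if train:
                    m = gy.size / gy.shape[1]
                    gx = gscale * (gy - (dbeta / m).reshape(sh)
                                   - xhat * (dgamma / m).reshape(sh))
                else:
                    gx = gscale * gy
                _accum(x, gx.astype(x.data.dtype))

        return _make(y, (x, gamma, beta), backward)

    def parameters(self):
        yield "gamma", self.gamma
        yield "beta", self.beta
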