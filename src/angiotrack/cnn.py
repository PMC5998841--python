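"""Minimal numpy CNN for 100x100 patch classification.

The classifier distinguishes cell from non-cell templates: two valid
convolutions (20 filters of 5x5, then 20 filters of 10x10), each
followed by ReLU and 2x2 max-pooling, then a 10-unit fully connected
layer with dropout and a 2-way softmax.  Training is plain SGD with
momentum on the cross-entropy loss, implemented with im2col matrix
multiplications in float32.

Because both pooling stages use stride 2, evaluating the network
densely over a whole image (convolutional application, with the fully
connected layers acting as large-kernel convolutions) is exactly
equivalent to evaluating patches on a stride-4 grid: score-map pixel
``(i, j)`` is the class probability of the 100x100 patch whose top-left
corner is ``(4*i, 4*j)``.  The sliding-window detector exploits this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class CnnArchitecture:
    """Layer sizes of the patch classifier."""

    input_size: int = 100
    conv1_filters: int = 20
    conv1_size: int = 5
    conv2_filters: int = 20
    conv2_size: int = 10
    pool: int = 2
    fc1_units: int = 10
    dropout: float = 0.5
    n_classes: int = 2

    @property
    def pooled_size(self) -> int:
        s = self.input_size
        s = (s - self.conv1_size + 1) // self.pool
        s = (s - self.conv2_size + 1) // self.pool
        return s


def _conv_forward(x, w, bias):
    """Valid NHWC convolution by shift-and-matmul.

    ``w`` has shape ``(C*k*k, F)`` flattened in ``(C, k, k)`` order.
    Accumulating one small matmul per kernel offset avoids the large
    strided im2col gather, which dominates runtime otherwise.
    """
    b, h, wd, c = x.shape
    f = w.shape[1]
    k = int(np.sqrt(w.shape[0] // c))
    ho, wo = h - k + 1, wd - k + 1
    wr = w.reshape(c, k, k, f)
    out = np.empty((b, ho, wo, f), dtype=np.float32)
    out[...] = bias
    for i in range(k):
        for j in range(k):
            xs = x[:, i:i + ho, j:j + wo, :].reshape(-1, c)
            out += (xs @ wr[:, i, j, :]).reshape(b, ho, wo, f)
    return out


def _conv_backward_w(x, dout, k):
    b, ho, wo, f = dout.shape
    c = x.shape[3]
    dw = np.empty((c, k, k, f), dtype=np.float32)
    d2 = dout.reshape(-1, f)
    for i in range(k):
        for j in range(k):
            xs = x[:, i:i + ho, j:j + wo, :].reshape(-1, c)
            dw[:, i, j, :] = xs.T @ d2
    db = dout.sum(axis=(0, 1, 2))
    return dw.reshape(c * k * k, f), db


def _conv_backward_x(dout, w, c_in, k):
    """Gradient w.r.t. the convolution input (scatter per offset)."""
    b, ho, wo, f = dout.shape
    wr = w.reshape(c_in, k, k, f)
    d2 = dout.reshape(-1, f)
    dx = np.zeros((b, ho + k - 1, wo + k - 1, c_in), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dx[:, i:i + ho, j:j + wo, :] += \
                (d2 @ wr[:, i, j, :].T).reshape(b, ho, wo, c_in)
    return dx


def _pool_forward(x, p=2):
    b, h, w, c = x.shape
    h2, w2 = h // p, w // p
    xc = x[:, :h2 * p, :w2 * p]
    xr = xc.reshape(b, h2, p, w2, p, c)
    out = xr.max(axis=(2, 4))
    return out, (xr, out, x.shape)


def _pool_backward(dout, cache, p=2):
    xr, out, xshape = cache
    mask = (xr == out[:, :, None, :, None, :])
    counts = mask.sum(axis=(2, 4), keepdims=True)
    grad = mask * (dout[:, :, None, :, None, :] / np.maximum(counts, 1))
    b, h2, _, w2, _, c = xr.shape
    dx = np.zeros(xshape, dtype=dout.dtype)
    dx[:, :h2 * p, :w2 * p] = grad.reshape(b, h2 * p, w2 * p, c)
    return dx


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class PatchCNN:
    """Trainable patch classifier (see module docstring)."""

    def __init__(self, arch: CnnArchitecture | None = None, rng=None):
        self.arch = arch or CnnArchitecture()
        rng = np.random.default_rng(rng if not isinstance(rng, np.random
                                    .Generator) else None) \
            if not isinstance(rng, np.random.Generator) else rng
        a = self.arch
        def he(fan_in, shape):
            return (rng.standard_normal(shape)
                    * np.sqrt(2.0 / fan_in)).astype(np.float32)
        k1, k2 = a.conv1_size, a.conv2_size
        self.w1 = he(k1 * k1, (k1 * k1 * 1, a.conv1_filters))
        self.b1 = np.zeros(a.conv1_filters, dtype=np.float32)
        self.w2 = he(k2 * k2 * a.conv1_filters,
                     (k2 * k2 * a.conv1_filters, a.conv2_filters))
        self.b2 = np.zeros(a.conv2_filters, dtype=np.float32)
        n_flat = a.pooled_size ** 2 * a.conv2_filters
        self.w3 = he(n_flat, (n_flat, a.fc1_units))
        self.b3 = np.zeros(a.fc1_units, dtype=np.float32)
        self.w4 = he(a.fc1_units, (a.fc1_units, a.n_classes))
        self.b4 = np.zeros(a.n_classes, dtype=np.float32)
        self._vel = {n: np.zeros_like(getattr(self, n))
                     for n in ("w1", "b1", "w2", "b2", "w3", "b3",
                               "w4", "b4")}
        self.norm_mean = 0.0
        self.norm_std = 1.0

    # -- forward / backward -------------------------------------------

    def _forward(self, x, train=False, rng=None):
        a = self.arch
        c1 = _conv_forward(x, self.w1, self.b1)
        r1 = np.maximum(c1, 0)
        p1, pc1 = _pool_forward(r1, a.pool)
        c2 = _conv_forward(p1, self.w2, self.b2)
        r2 = np.maximum(c2, 0)
        p2, pc2 = _pool_forward(r2, a.pool)
        n = a.pooled_size
        flat = p2[:, :n, :n, :].reshape(len(x), -1)
        f1 = flat @ self.w3 + self.b3
        h1 = np.maximum(f1, 0)
        if train and a.dropout > 0:
            drop = (rng.random(h1.shape) >= a.dropout).astype(np.float32) \
                / (1.0 - a.dropout)
            h1d = h1 * drop
        else:
            drop = None
            h1d = h1
        logits = h1d @ self.w4 + self.b4
        probs = _softmax(logits)
        cache = (x, c1, pc1, p1, c2, pc2, p2, flat, f1, h1d, drop)
        return probs, cache

    def _backward(self, probs, y, cache):
        a = self.arch
        x, c1, pc1, p1, c2, pc2, p2, flat, f1, h1d, drop = cache
        b = len(x)
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits = (dlogits / b).astype(np.float32)
        g = {}
        g["w4"] = h1d.T @ dlogits
        g["b4"] = dlogits.sum(axis=0)
        dh1 = dlogits @ self.w4.T
        if drop is not None:
            dh1 = dh1 * drop
        dh1 = dh1 * (f1 > 0)
        g["w3"] = flat.T @ dh1
        g["b3"] = dh1.sum(axis=0)
        dflat = dh1 @ self.w3.T
        n = a.pooled_size
        dp2 = np.zeros_like(p2)
        dp2[:, :n, :n, :] = dflat.reshape(b, n, n, a.conv2_filters)
        dr2 = _pool_backward(dp2, pc2, a.pool)
        dc2 = dr2 * (c2 > 0)
        g["w2"], g["b2"] = _conv_backward_w(p1, dc2, a.conv2_size)
        dp1 = _conv_backward_x(dc2, self.w2, a.conv1_filters, a.conv2_size)
        dr1 = _pool_backward(dp1, pc1, a.pool)
        dc1 = dr1 * (c1 > 0)
        g["w1"], g["b1"] = _conv_backward_w(x, dc1, a.conv1_size)
        return g

    # -- training / inference -----------------------------------------

    def _normalize(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[..., None]
        return (x - self.norm_mean) / self.norm_std

    def fit(self, patches, labels, epochs=6, lr=0.003, batch_size=32,
            momentum=0.9, rng=None, weight_decay=1e-4):
        """SGD with momentum on the cross-entropy loss."""
        rng = rng if isinstance(rng, np.random.Generator) \
            else np.random.default_rng(rng)
        x = np.asarray(patches, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        self.norm_mean = float(x.mean())
        self.norm_std = float(x.std() + 1e-6)
        x = (x - self.norm_mean) / self.norm_std
        y = np.asarray(labels, dtype=int)
        n = len(x)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                probs, cache = self._forward(x[idx], train=True, rng=rng)
                grads = self._backward(probs, y[idx], cache)
                for name, grad in grads.items():
                    if name.startswith("w"):
                        grad = grad + weight_decay * getattr(self, name)
                    v = self._vel[name]
                    v *= momentum
                    v -= lr * grad.astype(np.float32)
                    getattr(self, name)[...] += v
        return self

    def predict_proba(self, patches, batch_size=32) -> np.ndarray:
        x = self._normalize(patches)
        out = []
        for start in range(0, len(x), batch_size):
            probs, _ = self._forward(x[start:start + batch_size],
                                     train=False)
            out.append(probs)
        return np.vstack(out)

    def predict(self, patches) -> np.ndarray:
        return self.predict_proba(patches).argmax(axis=1)

    def score_map(self, image) -> tuple:
        """Dense cell-probability map over a full image.

        Returns ``(probs, stride, offset)`` where ``probs[i, j]`` is
        the positive-class probability of the patch with top-left
        corner ``(stride*i, stride*j)`` and centre offset ``offset``.
        """
        a = self.arch
        x = self._normalize(np.asarray(image, dtype=np.float32))
        c1 = _conv_forward(x, self.w1, self.b1)
        p1, _ = _pool_forward(np.maximum(c1, 0), a.pool)
        c2 = _conv_forward(p1, self.w2, self.b2)
        p2, _ = _pool_forward(np.maximum(c2, 0), a.pool)
        n = a.pooled_size
        v = sliding_window_view(p2, (n, n), axis=(1, 2))  # (1,Ho,Wo,C,n,n)
        ho, wo = v.shape[1], v.shape[2]
        # flatten in (H, W, C) order to match the fc weight layout
        cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)) \
            .reshape(ho * wo, -1)
        h1 = np.maximum(cols @ self.w3 + self.b3, 0)
        probs = _softmax(h1 @ self.w4 + self.b4)[:, 1].reshape(ho, wo)
        stride = a.pool * a.pool
        return probs, stride, a.input_size // 2
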