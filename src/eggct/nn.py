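"""Minimal 3D neural-network layers on numpy with explicit backpropagation.

Just enough machinery for the two segmentation architectures in this
package: 3D convolution (im2col + matmul), non-overlapping transposed 3D
convolution (kernel = stride), 2x2x2 max pooling, ReLU, channel dropout,
dense layers, global average pooling, softmax cross-entropy and MSE losses,
and Adam.  All tensors are float32 in (N, C, D, H, W) layout.  Layers cache
what the most recent forward pass needs, so call ``backward`` at most once
per ``forward``.
"""

from __future__ import annotations

import numpy as np

FLOAT = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=FLOAT)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3x3x3 (or 1x1x1) convolution, stride 1, 'same' zero padding.

    Computed as a sum over the k^3 kernel offsets: each offset contributes a
    (cout x cin) matmul against the correspondingly shifted input, which
    keeps every inner operation a contiguous copy plus a BLAS sgemm.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        fan_in = cin * k**3
        self.W = Param(rng.normal(0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)))
        self.b = Param(np.zeros(cout))
        self._xp = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    def _kernel(self) -> np.ndarray:
        return self.W.value.reshape(self.cout, self.cin, self.k, self.k, self.k)

    def forward(self, x, train=True):
        n, c, d, h, w = x.shape
        assert c == self.cin, (c, self.cin)
        k, p = self.k, self.pad
        x = np.ascontiguousarray(x, dtype=FLOAT)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        ker = self._kernel()
        out = np.empty((n, self.cout, d * h * w), dtype=FLOAT)
        out[:] = self.b.value[None, :, None]
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, :, a:a + d, bb:bb + h, cc:cc + w]).reshape(n, c, -1)
                    out += ker[None, :, :, a, bb, cc] @ xs
        self._xp, self._xshape = xp, x.shape
        return out.reshape(n, self.cout, d, h, w)

    def backward(self, g):
        n, c, d, h, w = self._xshape
        k, p = self.k, self.pad
        g = np.ascontiguousarray(g, dtype=FLOAT)
        gf = g.reshape(n, self.cout, -1)
        self.b.grad += gf.sum(axis=(0, 2))
        ker = self._kernel()
        gW = np.zeros_like(ker)
        gxp = np.zeros_like(self._xp)
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    xs = np.ascontiguousarray(
                        self._xp[:, :, a:a + d, bb:bb + h, cc:cc + w]).reshape(n, c, -1)
                    gW[:, :, a, bb, cc] = np.tensordot(gf, xs, axes=([0, 2], [0, 2]))
                    gx = (ker[None, :, :, a, bb, cc].transpose(0, 2, 1) @ gf)
                    gxp[:, :, a:a + d, bb:bb + h, cc:cc + w] += gx.reshape(n, c, d, h, w)
        self.W.grad += gW.reshape(self.cout, -1)
        self._xp = None
        return gxp[:, :, p:p + d, p:p + h, p:p + w] if p else gxp


class ConvTranspose3d(Layer):
    """Transposed 3D convolution with kernel size equal to stride, i.e. each
    input voxel paints a disjoint k^3 output block (the 3D U-Net
    up-convolution; also the stride-recovery layers of the FCN)."""

    def __init__(self, cin: int, cout: int, k: int = 2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.W = Param(rng.normal(0, np.sqrt(2.0 / cin), size=(cin, cout, k, k, k)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        n, c, d, h, w = x.shape
        k = self.k
        out = np.einsum("ncdhw,coijk->nodihjwk", x, self.W.value, optimize=True)
        out = out.reshape(n, self.cout, d * k, h * k, w * k)
        out += self.b.value[None, :, None, None, None]
        self._x = x
        return np.ascontiguousarray(out, dtype=FLOAT)

    def backward(self, g):
        n, c, d, h, w = self._x.shape
        k = self.k
        g8 = g.reshape(n, self.cout, d, k, h, k, w, k)
        self.b.grad += g.sum(axis=(0, 2, 3, 4))
        self.W.grad += np.einsum("ncdhw,nodihjwk->coijk", self._x, g8, optimize=True)
        gx = np.einsum("nodihjwk,coijk->ncdhw", g8, self.W.value, optimize=True)
        self._x = None
        return np.ascontiguousarray(gx, dtype=FLOAT)


class NearestUp(Layer):
    """Nearest-neighbor 2x upsampling (parameter-free alternative to the
    transposed convolution); its exact adjoint is 2x2x2 sum pooling."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train=True):
        k = self.k
        return np.ascontiguousarray(
            x.repeat(k, axis=2).repeat(k, axis=3).repeat(k, axis=4))

    def backward(self, g):
        n, c, d, h, w = g.shape
        k = self.k
        return g.reshape(n, c, d // k, k, h // k, k, w // k, k).sum(axis=(3, 5, 7))


class MaxPool3d(Layer):
    def __init__(self, k: int = 2):
        self.k = k
        self._idx = None
        self._shape = None

    def forward(self, x, train=True):
        k = self.k
        n, c, d, h, w = x.shape
        assert d % k == 0 and h % k == 0 and w % k == 0, x.shape
        xr = x.reshape(n, c, d // k, k, h // k, k, w // k, k)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // k, h // k, w // k, k**3)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._idx, self._shape = idx, x.shape
        return np.ascontiguousarray(out)

    def backward(self, g):
        n, c, d, h, w = self._shape
        k = self.k
        gr = np.zeros((n, c, d // k, h // k, w // k, k**3), dtype=FLOAT)
        np.put_along_axis(gr, self._idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, d // k, h // k, w // k, k, k, k)
        gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        self._idx = None
        return gr


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout3d(Layer):
    """Channel dropout: whole feature channels are zeroed with probability
    ``rate`` during training and the rest rescaled by 1/(1-rate)."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        assert 0 <= rate < 1
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=True):
        if not train or self.rate == 0:
            self._mask = None
            return x
        n, c = x.shape[:2]
        keep = (self.rng.random((n, c, 1, 1, 1)) >= self.rate).astype(FLOAT)
        self._mask = keep / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0, np.sqrt(2.0 / nin), size=(nout, nin)))
        self.b = Param(np.zeros(nout))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g):
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        x, self._x = self._x, None
        return g @ self.W.value


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C), averaging over all voxels."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, g):
        n, c, d, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None, None], self._shape) / (d * h * w)


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(scores: np.ndarray, labels: np.ndarray):
    """Voxel-wise cross-entropy.

    ``scores``: (N, K, D, H, W); ``labels``: (N, D, H, W) int codes.
    Returns (mean loss, gradient wrt scores).
    """
    n, k = scores.shape[:2]
    p = softmax(scores, axis=1)
    flat_p = p.transpose(0, 2, 3, 4, 1).reshape(-1, k)
    flat_l = labels.reshape(-1).astype(np.int64)
    nvox = flat_l.size
    eps = 1e-12
    loss = -np.log(flat_p[np.arange(nvox), flat_l] + eps).mean()
    gflat = flat_p.copy()
    gflat[np.arange(nvox), flat_l] -= 1.0
    gflat /= nvox
    g = gflat.reshape(n, *scores.shape[2:], k).transpose(0, 4, 1, 2, 3)
    return float(loss), np.ascontiguousarray(g, dtype=FLOAT)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    d = pred - np.asarray(target, dtype=FLOAT)
    return float((d**2).mean()), (2.0 / d.size) * d


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, *betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    if len(params) != len(state):
        raise ValueError("state length mismatch")
    for p, s in zip(params, state):
        p.value[...] = s
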