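"""Minimal 3D CNN building blocks in numpy (forward and backward).

Sized for the volumes this package trains on (cubic grids of a few dozen
voxels per axis), where a 3x3x3 convolution decomposed into 27 shifted
matmuls is fast enough on one CPU core.  Tensors are channels-last:
``(batch, depth, height, width, channels)``.  All layers follow the same
contract:

    out = layer.forward(x, train=..., rng=...)   # caches what backward needs
    dx  = layer.backward(dout)                   # fills layer.grads

Parameters live in ``layer.params`` (name -> float32 array) and gradients in
``layer.grads`` with matching keys; layers without parameters expose empty
dicts.  Evaluation-mode forward passes are deterministic and consume no
randomness.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Layer",
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "MaxPool3d2x",
    "Dropout",
    "Flatten",
    "Linear",
    "softmax",
    "cross_entropy_with_grad",
]

_SPATIAL_AXES = (1, 2, 3)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, zero padding 1 ("same").

    The kernel is stored as ``(3, 3, 3, c_in, c_out)`` and applied as one
    matmul per spatial offset, accumulating into the output — equivalent to
    im2col but without the expensive window gather.
    """

    K = 3

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        skip_input_grad: bool = False,
        stride: int = 1,
    ):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        # the input layer of a network never needs dx; skipping it saves the
        # most expensive scatter of the whole backward pass
        self.skip_input_grad = skip_input_grad
        if stride > 1 and not (skip_input_grad and c_in == 1):
            raise ValueError("stride > 1 is only supported for the input layer")
        self.stride = stride
        fan_in = c_in * self.K**3
        w = rng.standard_normal((self.K, self.K, self.K, c_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(c_out, dtype=np.float32)}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, d, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((b, d, h, w, 27 * c), dtype=x.dtype)
        for n, (i, j, k) in enumerate(product(range(3), repeat=3)):
            cols[..., n * c : (n + 1) * c] = xp[:, i : i + d, j : j + h, k : k + w, :]
        return cols.reshape(-1, 27 * c)

    def forward(self, x, *, train, rng):
        b, d, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if c == 1:
            # stencil path: direct correlation avoids materialising columns
            from scipy.ndimage import correlate

            s = self.stride
            do, ho, wo = (d + s - 1) // s, (h + s - 1) // s, (w + s - 1) // s
            out = np.empty((b, do, ho, wo, self.c_out), dtype=x.dtype)
            x0 = x[..., 0]
            for co in range(self.c_out):
                kernel = self.params["w"][:, :, :, 0, co].astype(x.dtype)
                full = correlate(x0, kernel[None], mode="constant", cval=0.0)
                out[..., co] = full[:, ::s, ::s, ::s]
            out += self.params["b"]
            if train:
                self._x1, self._shape = x, x.shape
            return out
        cols = self._im2col(x)
        out = cols @ self.params["w"].reshape(27 * c, self.c_out) + self.params["b"]
        if train:
            self._cols, self._shape = cols, x.shape
        return out.reshape(b, d, h, w, self.c_out)

    def _backward_stencil(self, dout):
        # dW by evaluating the x-dout correlation at each of the 27 offsets
        b, d, h, w, _ = self._shape
        s = self.stride
        xp = np.pad(self._x1[..., 0], ((0, 0), (1, 1), (1, 1), (1, 1)))
        dw = np.empty_like(self.params["w"])
        for i, j, k in product(range(3), repeat=3):
            xs = xp[:, i : i + d : s, j : j + h : s, k : k + w : s]
            dw[i, j, k, 0] = np.einsum("bdhw,bdhwo->o", xs, dout, optimize=False)
        self.grads["w"] = dw
        self.grads["b"] = dout.sum(axis=(0, 1, 2, 3))
        self._x1 = None
        if self.skip_input_grad:
            return np.zeros(self._shape, dtype=dout.dtype)
        dxp = np.zeros((b, d + 2, h + 2, w + 2), dtype=dout.dtype)
        wk = self.params["w"]
        for i, j, k in product(range(3), repeat=3):
            dxp[:, i : i + d, j : j + h, k : k + w] += dout @ wk[i, j, k, 0]
        return np.ascontiguousarray(dxp[:, 1:-1, 1:-1, 1:-1, None])

    def backward(self, dout):
        if self.c_in == 1:
            return self._backward_stencil(dout)
        assert self._cols is not None and self._shape is not None
        b, d, h, w, c = self._shape
        dmat = dout.reshape(-1, self.c_out)
        self.grads["w"] = (self._cols.T @ dmat).reshape(self.params["w"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        self._cols = None
        if self.skip_input_grad:
            return np.zeros(self._shape, dtype=dout.dtype)
        # dx: distribute dcols back over the 27 shifted positions
        dcols = dmat @ self.params["w"].reshape(27 * c, self.c_out).T
        dcols = dcols.reshape(b, d, h, w, 27 * c)
        dxp = np.zeros((b, d + 2, h + 2, w + 2, c), dtype=dout.dtype)
        for n, (i, j, k) in enumerate(product(range(3), repeat=3)):
            dxp[:, i : i + d, j : j + h, k : k + w, :] += dcols[..., n * c : (n + 1) * c]
        return np.ascontiguousarray(dxp[:, 1:-1, 1:-1, 1:-1, :])


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalisation with learned affine.

    No batch statistics, so behaviour is identical in train and eval mode
    and is well defined for batches of size 1 (small centers).
    """

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
        }

    def forward(self, x, *, train, rng):
        n = float(np.prod(x.shape[1:4]))
        s1 = np.einsum("bdhwc->bc", x, optimize=False)
        s2 = np.einsum("bdhwc,bdhwc->bc", x, x, optimize=False)
        mu = s1 / n
        var = np.maximum(s2 / n - mu * mu, 0.0)
        inv = 1.0 / np.sqrt(var + self.eps)
        bc = (slice(None), None, None, None, slice(None))
        xhat = (x - mu[bc]) * inv[bc]
        if train:
            self._xhat, self._inv = xhat, inv
        return xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        n = float(np.prod(xhat.shape[1:4]))
        self.grads["gamma"] = np.einsum("bdhwc,bdhwc->c", dout, xhat, optimize=False)
        self.grads["beta"] = np.einsum("bdhwc->c", dout, optimize=False)
        dxhat = dout * self.params["gamma"]
        s1 = np.einsum("bdhwc->bc", dxhat, optimize=False)
        s2 = np.einsum("bdhwc,bdhwc->bc", dxhat, xhat, optimize=False)
        bc = (slice(None), None, None, None, slice(None))
        dx = (inv[bc] / n) * (n * dxhat - s1[bc] - xhat * s2[bc])
        self._xhat = self._inv = None
        return dx.astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x, *, train, rng):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool3d2x(Layer):
    """2x2x2 max pooling, stride 2, floor mode (odd trailing voxels dropped).

    Backward routes each output gradient to the first (lowest-offset) voxel
    attaining the window maximum, so tied maxima are not double-counted.
    """

    _OFFSETS = list(product((0, 1), repeat=3))

    def forward(self, x, *, train, rng):
        b, d, h, w, c = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xc = x[:, : 2 * d2, : 2 * h2, : 2 * w2, :]
        views = [xc[:, a::2, bb::2, cc::2, :] for a, bb, cc in self._OFFSETS]
        out = views[0]
        for v in views[1:]:
            out = np.maximum(out, v)
        if train:
            self._x, self._out = x, out
        return np.ascontiguousarray(out)

    def backward(self, dout):
        x, out = self._x, self._out
        b, d, h, w, c = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dx = np.zeros_like(x)
        dxc = dx[:, : 2 * d2, : 2 * h2, : 2 * w2, :]
        xc = x[:, : 2 * d2, : 2 * h2, : 2 * w2, :]
        taken = np.zeros(out.shape, dtype=bool)
        for a, bb, cc in self._OFFSETS:
            view = xc[:, a::2, bb::2, cc::2, :]
            hit = (view == out) & ~taken
            dxc[:, a::2, bb::2, cc::2, :] += np.where(hit, dout, 0.0)
            taken |= hit
        self._x = self._out = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, *, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training forward with dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    def forward(self, x, *, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(n_out, dtype=np.float32)}

    def forward(self, x, *, train, rng):
        if train:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["w"].T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(logits.dtype)
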