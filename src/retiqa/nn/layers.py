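"""Layers with explicit forward/backward passes.

Tensors are ``(N, C, H, W)`` float arrays.  Every layer caches what its
backward pass needs during forward; backward must be called with the most
recent forward's cache still in place.  ``mode`` is one of ``"train"``,
``"eval"`` or ``"mc"``; layers that draw randomness consume the generator
passed to ``forward``.
"""

from __future__ import annotations

import numpy as np

MODES = ("train", "eval", "mc")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


class Module:
    """Base class: leaves hold ``params`` (trainable) and ``buffers`` (state)."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, mode: str, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, pad_value: float = 0.0):
    """Unfold ``(N, C, H, W)`` into ``(N, C*kh*kw, out_h*out_w)`` patches."""
    n, c, h, w = x.shape
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(
        x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value
    )
    cols = np.empty((n, c, kh, kw, out_h, out_w), dtype=x.dtype)
    for i in range(kh):
        i_max = i + stride * out_h
        for j in range(kw):
            j_max = j + stride * out_w
            cols[:, :, i, j] = xp[:, :, i:i_max:stride, j:j_max:stride]
    return cols.reshape(n, c * kh * kw, out_h * out_w), (out_h, out_w)


def col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Fold patch gradients back onto the input, accumulating overlaps."""
    n, c, h, w = x_shape
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    dcols = dcols.reshape(n, c, kh, kw, out_h, out_w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        i_max = i + stride * out_h
        for j in range(kw):
            j_max = j + stride * out_w
            dxp[:, :, i:i_max:stride, j:j_max:stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    """2-D convolution (no bias; always followed by a norm layer here)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, *, rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in))
        self.params["W"] = w.astype(dtype)
        self.zero_grad()

    def forward(self, x, mode, rng=None):
        _check_mode(mode)
        self._x_shape = x.shape
        cols, (oh, ow) = im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        self._cols = cols if mode == "train" else None
        out = np.matmul(self.params["W"], cols)
        return out.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dout):
        n, _, oh, ow = dout.shape
        dflat = dout.reshape(n, self.c_out, oh * ow)
        self.grads["W"] += np.einsum("nol,nkl->ok", dflat, self._cols)
        dcols = np.matmul(self.params["W"].T, dflat)
        return col2im(dcols, self._x_shape, self.kernel, self.kernel, self.stride, self.pad)

    def n_params(self) -> int:
        return self.params["W"].size


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.buffers["running_mean"] = np.zeros(c, dtype=dtype)
        self.buffers["running_var"] = np.ones(c, dtype=dtype)
        self.zero_grad()

    def forward(self, x, mode, rng=None):
        _check_mode(mode)
        if mode == "train":
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] *= 1 - m
            self.buffers["running_mean"] += m * mean
            self.buffers["running_var"] *= 1 - m
            self.buffers["running_var"] += m * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if mode == "train":
            self._xhat, self._ivar = xhat, ivar
        return self.params["gamma"][None, :, None, None] * xhat + \
            self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, ivar = self._xhat, self._ivar
        n_eff = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * ivar[None, :, None, None]
        return dx


class ReLU(Module):
    def forward(self, x, mode, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout2d(Module):
    """Channel dropout: whole feature maps are dropped, survivors rescaled.

    Active in ``train`` and ``mc`` modes; the identity in ``eval``.
    """

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, mode, rng=None):
        _check_mode(mode)
        if mode == "eval" or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("stochastic forward pass requires a random generator")
        keep = 1.0 - self.rate
        mask = (rng.random((x.shape[0], x.shape[1], 1, 1)) < keep) / keep
        self._mask = mask.astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1) -> None:
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, mode, rng=None):
        n, c, h, w = x.shape
        cols, (oh, ow) = im2col(
            x, self.kernel, self.kernel, self.stride, self.pad, pad_value=-np.inf
        )
        cols = cols.reshape(n, c, self.kernel * self.kernel, oh * ow)
        self._argmax = cols.argmax(axis=2)
        self._x_shape = x.shape
        self._out_hw = (oh, ow)
        out = np.take_along_axis(cols, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]
        return out.reshape(n, c, oh, ow)

    def backward(self, dout):
        n, c, h, w = self._x_shape
        oh, ow = self._out_hw
        k2 = self.kernel * self.kernel
        dcols = np.zeros((n, c, k2, oh * ow), dtype=dout.dtype)
        np.put_along_axis(
            dcols, self._argmax[:, :, None, :], dout.reshape(n, c, 1, oh * ow), axis=2
        )
        return col2im(
            dcols.reshape(n, c * k2, oh * ow), self._x_shape,
            self.kernel, self.kernel, self.stride, self.pad,
        )


class GlobalAvgPool(Module):
    def forward(self, x, mode, rng=None):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / self._hw


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, *, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(1.0 / c_in), (c_out, c_in)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.zero_grad()

    def forward(self, x, mode, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]
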