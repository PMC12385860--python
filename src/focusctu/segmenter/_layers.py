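"""Minimal numpy building blocks for the 3-D U-Net.

All tensors are channels-first ``(C, X, Y, Z)`` float32. Convolutions are
3×3×3, stride 1, zero-padded ("same"), implemented as im2col matrix
products; the input gradient is the correlation of the output gradient
with the channel-transposed, spatially flipped kernel (the exact adjoint).
Layers cache what their backward pass needs and accumulate parameter
gradients in ``g<name>`` attributes.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# float32 by default; tests may switch to float64 for high-precision gradient checks
DTYPE = np.float32


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, X, Y, Z) -> (X*Y*Z, C*27) patch matrix for a 3^3 'same' window."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    v = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (C, X, Y, Z, 3,3,3)
    C = x.shape[0]
    n = x.shape[1] * x.shape[2] * x.shape[3]
    return np.ascontiguousarray(v.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(n, C * 27)


class Layer:
    def param_items(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """name -> (parameter, gradient) pairs; empty for stateless layers."""
        return {}


class Conv3D(Layer):
    """3×3×3 convolution (cross-correlation), stride 1, same padding."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 27))
        self.W = rng.normal(0.0, std, (cout, cin, 3, 3, 3)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        cout = self.W.shape[0]
        y = self._cols @ self.W.reshape(cout, -1).T + self.b
        return np.ascontiguousarray(y.T).reshape(cout, *x.shape[1:])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cout = self.W.shape[0]
        dym = dy.reshape(cout, -1).T  # (N, cout)
        self.gW[...] = (dym.T @ self._cols).reshape(self.W.shape)
        self.gb[...] = dym.sum(axis=0)
        Wt = np.ascontiguousarray(
            self.W.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        )  # (cin, cout, 3,3,3)
        cols_dy = _im2col(dy)
        cin = self._shape[0]
        dx = cols_dy @ Wt.reshape(cin, -1).T
        self._cols = None
        return np.ascontiguousarray(dx.T).reshape(self._shape)

    def param_items(self):
        return {"W": (self.W, self.gW), "b": (self.b, self.gb)}


class Conv1x1(Layer):
    """1×1×1 projection (the classification head)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, std, (cout, cin)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.tensordot(self.W, x, axes=(1, 0)) + self.b[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW[...] = np.tensordot(dy, self._x, axes=((1, 2, 3), (1, 2, 3)))
        self.gb[...] = dy.sum(axis=(1, 2, 3))
        dx = np.tensordot(self.W.T, dy, axes=(1, 0))
        self._x = None
        return dx

    def param_items(self):
        return {"W": (self.W, self.gW), "b": (self.b, self.gb)}


class InstanceNorm(Layer):
    """Per-channel normalization over the spatial axes, with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (1, 2, 3)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma[:, None, None, None] * xhat + self.beta[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        ax = (1, 2, 3)
        n = dy[0].size
        self.ggamma[...] = (dy * xhat).sum(axis=ax)
        self.gbeta[...] = dy.sum(axis=ax)
        dxhat = dy * self.gamma[:, None, None, None]
        # dx = inv_std * (dxhat - mean(dxhat) - xhat * mean(dxhat * xhat))
        m1 = dxhat.mean(axis=ax, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=ax, keepdims=True)
        dx = inv_std * (dxhat - m1 - xhat * m2)
        self._cache = None
        return dx.astype(DTYPE)

    def param_items(self):
        return {"gamma": (self.gamma, self.ggamma), "beta": (self.beta, self.gbeta)}


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2×2×2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, X, Y, Z = x.shape
        xr = x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2)
        xr = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
            C, X // 2, Y // 2, Z // 2, 8
        )
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, X, Y, Z = self._in_shape
        flat = np.zeros((C, X // 2, Y // 2, Z // 2, 8), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(C, X // 2, Y // 2, Z // 2, 2, 2, 2)
        dx = flat.transpose(0, 1, 4, 2, 5, 3, 6).reshape(C, X, Y, Z)
        self._arg = None
        return np.ascontiguousarray(dx)


class Upsample2(Layer):
    """Nearest-neighbour ×2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, X, Y, Z = dy.shape
        return dy.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(2, 4, 6))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def dice_loss_and_grad(
    probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-5
) -> Tuple[float, np.ndarray]:
    """Categorical Dice loss and its gradient w.r.t. the probabilities.

    loss = 1 − mean over classes of (2·Σ p·g + ε)/(Σp + Σg + ε).
    Classes are weighted equally; ε keeps empty classes defined and bounds
    the loss in [0, 1].
    """
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {onehot.shape}")
    C = probs.shape[0]
    ax = tuple(range(1, probs.ndim))
    inter = (probs * onehot).sum(axis=ax)
    sums = probs.sum(axis=ax) + onehot.sum(axis=ax)
    dice = (2.0 * inter + eps) / (sums + eps)
    loss = 1.0 - dice.mean()
    # d(dice_c)/d(p_ci) = (2 g_ci (sums_c+eps) - (2 inter_c + eps)) / (sums_c+eps)^2
    denom = (sums + eps) ** 2
    shape = (C,) + (1,) * (probs.ndim - 1)
    dprobs = -(
        2.0 * onehot * (sums + eps).reshape(shape) - (2.0 * inter + eps).reshape(shape)
    ) / (C * denom.reshape(shape))
    return float(loss), dprobs.astype(DTYPE)


def softmax_dice_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Chain a probability-space gradient through the channel softmax."""
    dot = (dprobs * probs).sum(axis=0, keepdims=True)
    return (probs * (dprobs - dot)).astype(DTYPE)
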