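"""A compact 3-D U-Net in plain numpy.

Encoder–decoder with skip connections: ``depth`` resolution levels, two
3×3×3 conv (+ instance norm) + ReLU blocks per level, 2×2×2 max pooling
down, nearest-neighbour upsampling + skip concatenation up, and a 1×1×1
classification head with channel softmax. Channel width doubles per level.
Gradients are computed by hand layer-by-layer (verified against finite
differences in the test suite), so the network trains without any deep
learning framework; it is deliberately small and CPU-friendly.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from ._layers import (
    Conv1x1,
    Conv3D,
    InstanceNorm,
    Layer,
    MaxPool2,
    ReLU,
    Upsample2,
    dice_loss_and_grad,
    softmax_channels,
    softmax_dice_backward,
)


class _ConvBlock(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, use_norm: bool):
        self.layers: List[Layer] = []
        for c_in in (cin, cout):
            self.layers.append(Conv3D(c_in, cout, rng))
            if use_norm:
                self.layers.append(InstanceNorm(cout))
            self.layers.append(ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parametric(self) -> List[Layer]:
        return [l for l in self.layers if l.param_items()]


class UNet3D:
    """See module docstring. ``depth`` counts resolution levels (>= 2)."""

    def __init__(
        self,
        in_channels: int = 1,
        n_classes: int = 4,
        depth: int = 2,
        base_channels: int = 8,
        use_instance_norm=True,
        seed: int = 0,
    ):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        ch = [base_channels * 2 ** l for l in range(depth)]
        self.depth = depth

        # "hybrid" keeps the full-resolution blocks un-normalized so the
        # absolute intensity level (which separates organs of identical
        # shape) survives; instance norm would make the features invariant
        # to affine intensity maps of the crop.
        def norm_at(level: int) -> bool:
            if use_instance_norm == "hybrid":
                return level > 0
            return bool(use_instance_norm)

        self.enc = [
            _ConvBlock(in_channels if l == 0 else ch[l - 1], ch[l], rng, norm_at(l))
            for l in range(depth)
        ]
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = [Upsample2() for _ in range(depth - 1)]
        self.dec = [
            _ConvBlock(ch[l] + ch[l + 1], ch[l], rng, norm_at(l))
            for l in range(depth - 1)
        ]
        self.head = Conv1x1(ch[0], n_classes, rng)
        self._skip_channels = ch

    # ---- parameter plumbing -------------------------------------------------

    def parametric_layers(self) -> List[Layer]:
        out: List[Layer] = []
        for blk in self.enc:
            out.extend(blk.parametric())
        for blk in self.dec:
            out.extend(blk.parametric())
        out.append(self.head)
        return out

    def get_state(self) -> List[Dict[str, np.ndarray]]:
        return [
            {k: p.copy() for k, (p, _) in layer.param_items().items()}
            for layer in self.parametric_layers()
        ]

    def set_state(self, state: List[Dict[str, np.ndarray]]) -> None:
        layers = self.parametric_layers()
        if len(layers) != len(state):
            raise ValueError("state does not match the architecture")
        for layer, params in zip(layers, state):
            for k, (p, _) in layer.param_items().items():
                p[...] = params[k]

    # ---- forward / backward -------------------------------------------------

    def forward_probs(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (n_classes, X, Y, Z) for an input (1, X, Y, Z)."""
        self._check_divisible(x)
        skips = []
        h = x
        for l in range(self.depth - 1):
            h = self.enc[l].forward(h)
            skips.append(h)
            h = self.pools[l].forward(h)
        h = self.enc[-1].forward(h)
        for l in reversed(range(self.depth - 1)):
            h = self.ups[l].forward(h)
            h = np.concatenate([skips[l], h], axis=0)
            h = self.dec[l].forward(h)
        logits = self.head.forward(h)
        self._skips_shapes = [s.shape[0] for s in skips]
        return softmax_channels(logits)

    def loss_and_grad(self, x: np.ndarray, onehot: np.ndarray, eps: float = 1e-5) -> float:
        """Dice loss for one patch; leaves parameter gradients in the layers."""
        probs = self.forward_probs(x)
        loss, dprobs = dice_loss_and_grad(probs, onehot, eps)
        dh = self.head.backward(softmax_dice_backward(probs, dprobs))
        dskips = [None] * (self.depth - 1)
        for l in range(self.depth - 1):
            dh = self.dec[l].backward(dh)
            c = self._skips_shapes[l]
            dskips[l] = dh[:c]
            dh = self.ups[l].backward(dh[c:])
        dh = self.enc[-1].backward(dh)
        for l in reversed(range(self.depth - 1)):
            dh = self.pools[l].backward(dh)
            dh = dh + dskips[l]
            dh = self.enc[l].backward(dh)
        return loss

    def _check_divisible(self, x: np.ndarray) -> None:
        div = 2 ** (self.depth - 1)
        if any(d % div for d in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be divisible by {div} for depth {self.depth}"
            )


class RMSProp:
    """RMSProp with running squared-gradient normalization."""

    def __init__(self, net: UNet3D, learning_rate: float, rho: float = 0.9, eps: float = 1e-8):
        self.net = net
        self.lr = learning_rate
        self.rho = rho
        self.eps = eps
        self._cache: List[Dict[str, np.ndarray]] = [
            {k: np.zeros_like(p) for k, (p, _) in layer.param_items().items()}
            for layer in net.parametric_layers()
        ]

    def step(self) -> None:
        for layer, cache in zip(self.net.parametric_layers(), self._cache):
            for k, (p, g) in layer.param_items().items():
                c = cache[k]
                c[...] = self.rho * c + (1.0 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(c) + self.eps)
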