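"""Compact CPU convolutional-network engine used by the segmentation module.

Implements exactly the pieces the capillary segmentation network needs —
3×3 same-padding convolutions, ReLU, 2×2 max pooling, 2×2 stride-2
up-convolutions (transposed convolutions), channel concatenation, a 1×1
output convolution, softmax with class-weighted categorical cross-entropy,
and the Adam optimizer — as plain numpy with hand-derived backward passes.

Array layout is channels-last: activations are ``(B, H, W, C)`` float64.
Convolutions are evaluated with stride-tricks sliding windows contracted by
``np.tensordot``; backward passes recompute the window view (a zero-copy
view) instead of caching column matrices, keeping memory modest.

Every layer's gradient is verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "UpConv2",
    "Conv1x1",
    "Adam",
    "weighted_softmax_cross_entropy",
    "UNet",
]


def _windows3(xp: np.ndarray) -> np.ndarray:
    """(B, H+2, W+2, C) padded input -> (B, H, W, 3, 3, C) view."""
    from numpy.lib.stride_tricks import sliding_window_view

    v = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (B, H, W, C, 3, 3)
    return v.transpose(0, 1, 2, 4, 5, 3)


class Conv3x3:
    """3×3 convolution, stride 1, zero ("same") padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * c_in))
        self.w = rng.normal(0.0, std, (3, 3, c_in, c_out))
        self.b = np.zeros(c_out)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        return np.tensordot(_windows3(xp), self.w, axes=([3, 4, 5], [0, 1, 2])) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = np.tensordot(_windows3(self._xp), dy, axes=([0, 1, 2], [0, 1, 2]))
        self.db = dy.sum(axis=(0, 1, 2))
        dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (0, 0)))
        w_flip = self.w[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,Cout,Cin)
        self._xp = None
        return np.tensordot(_windows3(dyp), w_flip, axes=([3, 4, 5], [0, 1, 2]))

    def params(self):
        return [("w", self), ("b", self)]


class Conv1x1:
    """1×1 convolution mapping features to per-pixel class scores."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, (c_in, c_out))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = np.tensordot(self._x, dy, axes=([0, 1, 2], [0, 1, 2]))
        self.db = dy.sum(axis=(0, 1, 2))
        self._x = None
        return dy @ self.w.T

    def params(self):
        return [("w", self), ("b", self)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dy, 0.0)
        self._mask = None
        return out

    def params(self):
        return []


class MaxPool2:
    """2×2 max pooling, stride 2; requires even spatial dimensions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        blocks = x.reshape(b, h // 2, 2, w // 2, 2, c)
        flat = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(b, h // 2, w // 2, c, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        flat = np.zeros((b, h // 2, w // 2, c, 4))
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        blocks = flat.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._arg = None
        return blocks.reshape(b, h, w, c)

    def params(self):
        return []


class UpConv2:
    """2×2 stride-2 transposed convolution (learned 2× upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, (2, 2, c_in, c_out))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        b, h, w, _ = x.shape
        y = np.tensordot(x, self.w, axes=([3], [2]))  # (B,h,w,2,2,Cout)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(b, 2 * h, 2 * w, -1)
        return y + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, H, W, c_out = dy.shape
        blocks = dy.reshape(b, H // 2, 2, W // 2, 2, c_out).transpose(0, 1, 3, 2, 4, 5)
        self.dw = np.tensordot(self._x, blocks, axes=([0, 1, 2], [0, 1, 2]))
        self.dw = self.dw.transpose(1, 2, 0, 3)  # (2,2,Cin,Cout)
        self.db = dy.sum(axis=(0, 1, 2))
        dx = np.tensordot(blocks, self.w, axes=([3, 4, 5], [0, 1, 3]))
        self._x = None
        return dx

    def params(self):
        return [("w", self), ("b", self)]


def weighted_softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted categorical cross-entropy over per-pixel softmax scores.

    ``logits``: (B, H, W, K); ``targets``: (B, H, W) integer labels;
    ``class_weights``: (K,).  The loss is the weighted mean of per-pixel
    negative log-likelihoods (normalized by the total weight, so its scale
    does not depend on the class balance).  Returns (loss, dlogits).
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    onehot = np.eye(logits.shape[-1])[targets]
    wpix = class_weights[targets]
    total_w = wpix.sum()
    logp = np.log(np.clip((p * onehot).sum(axis=-1), 1e-12, None))
    loss = float(-(wpix * logp).sum() / total_w)
    dlogits = wpix[..., None] * (p - onehot) / total_w
    return loss, dlogits


class Adam:
    """Adam optimizer over a list of (attr-name, layer) parameter handles."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(layer, name)) for name, layer in params]
        self.v = [np.zeros_like(getattr(layer, name)) for name, layer in params]

    def step(self) -> None:
        self.t += 1
        for i, (name, layer) in enumerate(self.params):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(layer, name)
            setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class _Block:
    """Two 3×3 conv + ReLU pairs at one resolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c1 = Conv3x3(c_in, c_out, rng)
        self.r1 = ReLU()
        self.c2 = Conv3x3(c_out, c_out, rng)
        self.r2 = ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))

    def params(self):
        return self.c1.params() + self.c2.params()


class UNet:
    """Encoder–decoder segmentation network with skip connections.

    Four resolution levels: contracting blocks with ``filters`` channels and
    2×2 max pooling between levels (spatial size input → /2 → /4 → /8 at the
    bottleneck), then a mirrored expanding path of 2×2 up-convolutions, each
    concatenated with the encoder features of matching resolution, and a 1×1
    convolution to ``n_classes`` per-pixel scores at input resolution.
    Input spatial dimensions must be divisible by 2^(levels−1).
    """

    def __init__(self, filters: tuple[int, ...] = (32, 64, 128, 256),
                 n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.filters = tuple(filters)
        f = self.filters
        self.enc = []
        c_in = 1
        for c in f:
            self.enc.append(_Block(c_in, c, rng))
            c_in = c
        self.pools = [MaxPool2() for _ in range(len(f) - 1)]
        self.ups = []
        self.dec = []
        for i in range(len(f) - 2, -1, -1):
            self.ups.append(UpConv2(c_in, f[i], rng))
            self.dec.append(_Block(2 * f[i], f[i], rng))
            c_in = f[i]
        self.head = Conv1x1(c_in, n_classes, rng)

    def _check_input(self, x: np.ndarray) -> None:
        div = 2 ** (len(self.filters) - 1)
        _, h, w, _ = x.shape
        if h % div or w % div:
            raise ValueError(f"input spatial size must be divisible by {div}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_input(x)
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[-1])
            x = dec.forward(np.concatenate([skip, x], axis=-1))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, dec, c_skip in zip(reversed(self.ups), reversed(self.dec),
                                   reversed(self._skip_channels)):
            dcat = dec.backward(dx)
            dskips.append(dcat[..., :c_skip])
            dx = up.backward(dcat[..., c_skip:])
        dskips.reverse()  # now ordered from deepest skip to shallowest
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                dx = self.pools[i].backward(dx)
                dx = dx + dskips[len(self.pools) - 1 - i]
            dx = self.enc[i].backward(dx)

    def params(self):
        out = []
        for block in self.enc + self.dec:
            out += block.params()
        for up in self.ups:
            out += up.params()
        out += self.head.params()
        return out

    def get_state(self) -> list[np.ndarray]:
        return [getattr(layer, name).copy() for name, layer in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (name, layer), arr in zip(self.params(), state):
            setattr(layer, name, arr.copy())

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel softmax probabilities, (B, H, W, K)."""
        logits = self.forward(np.asarray(x, dtype=np.float64))
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=-1, keepdims=True)
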