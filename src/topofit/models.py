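"""A small differentiable U-net predictor for 2D images and 3D volumes.

The predictor maps an input field ``X`` to a probability map ``S = f(X; w)``
of the same shape with values in (0, 1).  It is a conventional
encoder-decoder with skip concatenations: each level applies two 3^d
convolutions with ReLU, downsampling is 2x average pooling, upsampling is
2x nearest-neighbour, and a final 1-voxel convolution with a sigmoid
produces the probability map.

Forward and backward passes are written explicitly on numpy arrays: calling
:meth:`Predictor.forward` caches intermediates, and
:meth:`Predictor.backward` accepts an upstream gradient dL/dS and
accumulates exact parameter gradients.  This is all the differentiability
the training frameworks need — every loss in this package (MSE, soft Dice,
the topological loss) supplies its gradient with respect to the probability
map in closed form, and the network routes it back to the weights.

Everything is seeded and deterministic: two predictors built with the same
architecture and seed produce bit-identical outputs.
"""

from __future__ import annotations

import copy
import os
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Predictor", "Adam", "build_unet", "clone_predictor"]


class Param:
    """A trainable array with its accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Conv:
    """Same-padded convolution with kernel 3^d (or 1^d for the head)."""

    def __init__(self, c_in: int, c_out: int, d: int, kernel: int,
                 rng: np.random.Generator, *, gain: float = 2.0):
        k = (kernel,) * d
        fan_in = c_in * int(np.prod(k))
        self.W = Param(rng.normal(0.0, np.sqrt(gain / fan_in), size=(c_out, c_in, *k)))
        self.b = Param(np.zeros(c_out))
        self.d = d
        self.kernel = kernel
        self._cols: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def _correlate(x: np.ndarray, W: np.ndarray, b: np.ndarray, kernel: int):
        """y[co] = sum_ci x[ci] * W[co,ci] (same padding); returns (y, cols)."""
        d = x.ndim - 1
        spatial = x.shape[1:]
        pad = kernel // 2
        xp = np.pad(x, ((0, 0),) + ((pad, pad),) * d)
        win = sliding_window_view(xp, (kernel,) * d, axis=tuple(range(1, d + 1)))
        # win: (Cin, *S, k...) -> cols: (P, Cin*K)
        cols = np.moveaxis(win, 0, d).reshape(int(np.prod(spatial)), -1)
        Wm = W.reshape(W.shape[0], -1)
        y = cols @ Wm.T + b
        y = np.moveaxis(y.reshape(*spatial, W.shape[0]), -1, 0)
        return y, cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, cols = self._correlate(x, self.W.value, self.b.value, self.kernel)
        self._cols = cols
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out = dy.shape[0]
        spatial = dy.shape[1:]
        dy_mat = np.moveaxis(dy, 0, -1).reshape(int(np.prod(spatial)), c_out)
        self.W.grad += (dy_mat.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dy_mat.sum(axis=0)
        # dx: correlate dy with the channel-transposed, spatially flipped kernel
        Wt = np.swapaxes(self.W.value, 0, 1)
        Wt = Wt[(slice(None), slice(None)) + (slice(None, None, -1),) * self.d]
        dx, _ = self._correlate(dy, Wt, np.zeros(Wt.shape[0]), self.kernel)
        self._cols = None
        return dx


class _ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _avgpool2(x: np.ndarray) -> np.ndarray:
    d = x.ndim - 1
    for ax in range(1, d + 1):
        n = x.shape[ax]
        x = x.reshape(x.shape[:ax] + (n // 2, 2) + x.shape[ax + 1:]).mean(axis=ax + 1)
    return x


def _avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    d = dy.ndim - 1
    g = dy / (2 ** d)
    for ax in range(1, d + 1):
        g = np.repeat(g, 2, axis=ax)
    return g


def _upsample2(x: np.ndarray) -> np.ndarray:
    for ax in range(1, x.ndim):
        x = np.repeat(x, 2, axis=ax)
    return x


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    d = dy.ndim - 1
    for ax in range(1, d + 1):
        n = dy.shape[ax]
        dy = dy.reshape(dy.shape[:ax] + (n // 2, 2) + dy.shape[ax + 1:]).sum(axis=ax + 1)
    return dy


class _ConvBlock:
    """conv 3^d -> ReLU -> conv 3^d -> ReLU."""

    def __init__(self, c_in, c_out, d, rng):
        self.layers = [
            _Conv(c_in, c_out, d, 3, rng), _ReLU(),
            _Conv(c_out, c_out, d, 3, rng), _ReLU(),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# The U-net predictor
# ---------------------------------------------------------------------------


class Predictor:
    """A seeded U-net ``f(X; w)`` mapping a field to a probability map.

    Parameters
    ----------
    spatial_dims : 2 or 3
    depth : number of pooling steps; input sides must be divisible by 2**depth
    base_channels : channels at the top level (doubled per level going down)
    seed : initialisation seed
    """

    def __init__(self, spatial_dims: int, depth: int, base_channels: int, seed: int):
        if spatial_dims not in (2, 3):
            raise ValueError("spatial_dims must be 2 or 3")
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.spatial_dims = spatial_dims
        self.depth = depth
        self.base_channels = base_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = spatial_dims
        ch = [base_channels * 2 ** i for i in range(depth + 1)]
        self.enc = [_ConvBlock(1 if i == 0 else ch[i - 1], ch[i], d, rng)
                    for i in range(depth)]
        self.bottleneck = _ConvBlock(ch[depth - 1], ch[depth], d, rng)
        self.dec = [_ConvBlock(ch[i + 1] + ch[i], ch[i], d, rng)
                    for i in reversed(range(depth))]
        self.head = _Conv(ch[0], 1, d, 1, rng, gain=1.0)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Param]:
        ps: list[Param] = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for blk in self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match architecture")
        for p, v in zip(params, state):
            p.value[...] = v

    def save(self, path: str | os.PathLike) -> None:
        np.savez(
            path,
            *self.state_dict(),
            meta=np.array([self.spatial_dims, self.depth, self.base_channels, self.seed]),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Predictor":
        with np.load(path) as z:
            meta = z["meta"]
            pred = cls(int(meta[0]), int(meta[1]), int(meta[2]), int(meta[3]))
            pred.load_state_dict([z[k] for k in z.files if k != "meta"])
        return pred

    # -- forward / backward -------------------------------------------------

    def _check_shape(self, shape: tuple[int, ...]) -> None:
        if len(shape) != self.spatial_dims:
            raise ValueError(f"expected a {self.spatial_dims}D input, got shape {shape}")
        div = 2 ** self.depth
        bad = [n for n in shape if n % div]
        if bad:
            need = [int(np.ceil(n / div) * div) for n in shape]
            raise ValueError(
                f"input shape {shape} not divisible by 2^depth={div}; "
                f"pad to {tuple(need)}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probability map for input field ``x``; caches for :meth:`backward`."""
        x = np.asarray(x, dtype=np.float64)
        self._check_shape(x.shape)
        h = x[None]  # channel axis
        skips = []
        for blk in self.enc:
            h = blk.forward(h)
            skips.append(h)
            h = _avgpool2(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for blk, skip in zip(self.dec, reversed(skips)):
            h = _upsample2(h)
            self._skip_channels.append((h.shape[0], skip.shape[0]))
            h = np.concatenate([h, skip], axis=0)
            h = blk.forward(h)
        logits = self.head.forward(h)
        s = _sigmoid(logits[0])
        self._s = s
        return s

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass without retaining the result for a backward call."""
        return self.forward(x)

    def backward(self, dS: np.ndarray) -> np.ndarray:
        """Backpropagate dL/dS; accumulates parameter grads, returns dL/dX."""
        s = self._s
        dy = (dS * s * (1.0 - s))[None]
        dy = self.head.backward(dy)
        dskips = []
        for blk, (c_up, c_skip) in zip(self.dec[::-1], self._skip_channels[::-1]):
            dy = blk.backward(dy)
            d_up, d_skip = dy[:c_up], dy[c_up:]
            dskips.append(d_skip)
            dy = _upsample2_backward(d_up)
        dy = self.bottleneck.backward(dy)
        for blk, d_skip in zip(self.enc[::-1], dskips[::-1]):
            dy = _avgpool2_backward(dy) + d_skip
            dy = blk.backward(dy)
        return dy[0]


def build_unet(spatial_dims: int, depth: int = 2, base_channels: int = 8,
               seed: int = 0) -> Predictor:
    """Build a seeded U-net predictor (see :class:`Predictor`)."""
    return Predictor(spatial_dims, depth, base_channels, seed)


def clone_predictor(pred: Predictor) -> Predictor:
    """Deep, independent copy: mutating the clone never affects the original."""
    return copy.deepcopy(pred)


class Adam:
    """Adaptive-moment gradient descent over a list of :class:`Param`."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
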