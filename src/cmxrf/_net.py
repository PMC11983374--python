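"""Minimal CNN/MLP building blocks in NumPy.

Float32 throughout, seeded He initialization, Adam optimizer, plain MSE.
Data layout is channels-last (N, H, W, C); a 3x3 same-padding
convolution is evaluated as nine shifted batched matmuls, which keeps
every inner product a contiguous BLAS call and avoids im2col copies -
the difference between an unusable and a perfectly workable CPU training
loop at this model size.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2D", "AvgPoolTo", "Flatten", "Dense", "Sequential", "Adam"]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 stride-1 same-padding convolution, channels-last.

    Weights are stored as (9, in_ch, out_ch), one slice per kernel
    offset (ky, kx) in row-major order.
    """

    def __init__(
        self, in_ch: int, out_ch: int, rng: np.random.Generator, first: bool = False
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.first = first  # first layer of the net: input gradient not needed
        self.W = _he_init(rng, (9, in_ch, out_ch), fan_in=in_ch * 9)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    # With few input channels the 9 shifted matmuls degenerate into
    # memory-bound outer products, so a single im2col GEMM wins there.
    @property
    def _use_im2col(self) -> bool:
        return self.in_ch <= 4

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        self._xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        if self._use_im2col:
            cols = np.empty((n, h, w, 9 * self.in_ch), dtype=np.float32)
            for k in range(9):
                ky, kx = divmod(k, 3)
                cols[..., k * self.in_ch : (k + 1) * self.in_ch] = self._xp[
                    :, ky : ky + h, kx : kx + w, :
                ]
            self._cols = cols.reshape(n * h * w, 9 * self.in_ch)
            out = self._cols @ self.W.reshape(9 * self.in_ch, self.out_ch) + self.b
            return out.reshape(n, h, w, self.out_ch)
        out = np.broadcast_to(self.b, (n, h, w, self.out_ch)).copy()
        for k in range(9):
            ky, kx = divmod(k, 3)
            out += self._xp[:, ky : ky + h, kx : kx + w, :] @ self.W[k]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = dout.shape
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        if self._use_im2col:
            dflat = dout.reshape(n * h * w, self.out_ch)
            self.grads[0][...] = (self._cols.T @ dflat).reshape(self.W.shape)
            if self.first:
                return dout  # unused upstream
            doutp = np.pad(dout, ((0, 0), (1, 1), (1, 1), (0, 0)))
            dx = np.zeros((n, h, w, self.in_ch), dtype=np.float32)
            for k in range(9):
                ky, kx = divmod(k, 3)
                dx += doutp[:, 2 - ky : 2 - ky + h, 2 - kx : 2 - kx + w, :] @ self.W[k].T
            return dx
        doutp = None if self.first else np.pad(dout, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dx = None if self.first else np.zeros((n, h, w, self.in_ch), dtype=np.float32)
        for k in range(9):
            ky, kx = divmod(k, 3)
            x_slice = self._xp[:, ky : ky + h, kx : kx + w, :]
            self.grads[0][k] = np.tensordot(x_slice, dout, axes=([0, 1, 2], [0, 1, 2]))
            if dx is not None:
                # transposed convolution: correlate dout with flipped kernel
                dx += doutp[:, 2 - ky : 2 - ky + h, 2 - kx : 2 - kx + w, :] @ self.W[k].T
        return dout if dx is None else dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, np.float32(0.0))


class MaxPool2D(Layer):
    """2x2 max pooling; odd trailing rows/columns are cropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2 * 2, w // 2 * 2
        self._in_shape = x.shape
        xc = x[:, :h2, :w2, :].reshape(n, h2 // 2, 2, w2 // 2, 2, c)
        out = xc.max(axis=(2, 4))
        self._mask = xc == out[:, :, None, :, None, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2 * 2, w // 2 * 2
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        spread = self._mask * dout[:, :, None, :, None, :]
        dx[:, :h2, :w2, :] = spread.reshape(n, h2, w2, c)
        return dx


class AvgPoolTo(Layer):
    """Average-pool (H, W) to a fixed target shape; identity when the
    input already matches.  Requires integer pooling factors."""

    def __init__(self, target: tuple[int, int]) -> None:
        super().__init__()
        self.target = target

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        th, tw = self.target
        if (h, w) == (th, tw):
            self._factors = (1, 1)
            return x
        if h % th or w % tw:
            raise ValueError(f"cannot pool {(h, w)} to {self.target} evenly")
        fh, fw = h // th, w // tw
        self._factors = (fh, fw)
        return x.reshape(n, th, fh, tw, fw, c).mean(axis=(2, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        fh, fw = self._factors
        if (fh, fw) == (1, 1):
            return dout
        scale = np.float32(1.0 / (fh * fw))
        return np.repeat(np.repeat(dout, fh, axis=1), fw, axis=2) * scale


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _he_init(rng, (n_in, n_out), fan_in=n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    backward_to_input = backward

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


class Adam:
    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)
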