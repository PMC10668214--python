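"""Minimal NumPy neural-network layers with manual backpropagation.

Only what the classifiers need: causal dilated 1-D convolutions, dense
layers, ReLU, dropout, softmax cross-entropy, the Adam optimizer and a
one-cycle learning-rate schedule.  Shapes follow the (batch, channels, time)
convention for convolutional layers and (batch, features) for dense layers.
"""

from __future__ import annotations

import math

import numpy as np

#: All network arithmetic runs in single precision: EEG dynamics do not need
#: more, and it roughly quadruples CPU throughput.
DTYPE = np.float32


class Layer:
    """Base class: parameterized layers expose ``params`` / ``grads`` lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class CausalConv1d(Layer):
    """Dilated 1-D convolution with left ("causal") zero padding.

    Output index t depends only on input indices <= t, so no information
    leaks from future to past.  Input/output length are equal.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.dilation = c_in, c_out, kernel, dilation
        scale = math.sqrt(2.0 / (c_in * kernel))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._xpad: np.ndarray | None = None

    @property
    def left_pad(self) -> int:
        return (self.kernel - 1) * self.dilation

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, _, t = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (self.left_pad, 0)))
        if train:
            self._xpad = xpad
        # windows[b, i, j, t] = xpad[b, i, j*d + t]; tensordot performs the GEMM
        sb, si, st = xpad.strides
        windows = np.lib.stride_tricks.as_strided(
            xpad,
            shape=(b, self.c_in, self.kernel, t),
            strides=(sb, si, self.dilation * st, st),
        )
        out = np.tensordot(self.w, windows, axes=((1, 2), (1, 2)))  # (c_out, b, t)
        return np.ascontiguousarray(out.transpose(1, 0, 2)) + self.b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._xpad is not None, "backward before forward(train=True)"
        b, _, t = grad.shape
        xpad = self._xpad
        sb, si, st = xpad.strides
        windows = np.lib.stride_tricks.as_strided(
            xpad,
            shape=(b, self.c_in, self.kernel, t),
            strides=(sb, si, self.dilation * st, st),
        )
        # dW[o,i,j] = sum_{b,t} grad[b,o,t] * windows[b,i,j,t]
        self.grads[0][...] = np.tensordot(grad, windows, axes=((0, 2), (0, 3)))
        self.grads[1][...] = grad.sum(axis=(0, 2))
        # input gradient is the correlation with the time-flipped kernel:
        # dx[b,i,u] = sum_{o,m} w[o,i,k-1-m] * grad[b,o,u+m*d]  (grad right-padded)
        gpad = np.pad(grad, ((0, 0), (0, 0), (0, self.left_pad)))
        gb, go, gt = gpad.strides
        gwin = np.lib.stride_tricks.as_strided(
            gpad,
            shape=(b, self.c_out, self.kernel, t),
            strides=(gb, go, self.dilation * gt, gt),
        )
        wflip = self.w[:, :, ::-1]
        dx = np.tensordot(wflip, gwin, axes=((0, 2), (1, 2)))  # (c_in, b, t)
        self._xpad = None
        return np.ascontiguousarray(dx.transpose(1, 0, 2))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng) -> None:
        super().__init__()
        scale = math.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        self._x = None
        return grad @ self.w.T


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        out = grad * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float, rng) -> None:
        super().__init__()
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            return x
        keep = 1.0 - self.p
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood; ``targets`` are integer class indices."""
    n = probs.shape[0]
    return float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())


def cross_entropy_grad(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the logits (softmax folded in)."""
    n = probs.shape[0]
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return grad / n


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 pct_start: float = 0.25, div: float = 25.0,
                 final_div: float = 1e4) -> float:
    """Cosine-annealed one-cycle schedule: warm up to ``max_lr`` then anneal.

    The warmup covers ``pct_start`` of all steps starting from ``max_lr/div``;
    the remainder anneals to ``max_lr/final_div``.
    """
    warm = max(int(total_steps * pct_start), 1)
    if step < warm:
        frac = step / warm
        lo = max_lr / div
        return lo + (max_lr - lo) * 0.5 * (1 - math.cos(math.pi * frac))
    frac = (step - warm) / max(total_steps - warm, 1)
    lo = max_lr / final_div
    return lo + (max_lr - lo) * 0.5 * (1 + math.cos(math.pi * frac))
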