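"""Temporal convolutional network (TCN) classifier.

Causal dilated 1-D convolutions organized in residual blocks, dilation
doubling per level, so that the receptive field covers the whole 256-sample
input window.  Classification pools the causal feature sequence by global
average pooling (GAP) and applies a dense softmax head; GAP keeps the
parameter count small and spreads the gradient over all time steps.
"""

from __future__ import annotations

import numpy as np

from iedscan.models._nn import CausalConv1d, Dense, Dropout, ReLU
from iedscan.models.base import ClassifierModel, register_architecture

DEFAULT_HP = {
    "n_levels": 5,
    "kernel_size": 7,
    "n_filters": 12,
    "dropout": 0.1,
}


class _TemporalBlock:
    """conv-relu-drop x2 with a residual connection (1x1 conv on width change)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 dropout: float, rng) -> None:
        self.conv1 = CausalConv1d(c_in, c_out, kernel, dilation, rng)
        self.relu1 = ReLU()
        self.drop1 = Dropout(dropout, rng)
        self.conv2 = CausalConv1d(c_out, c_out, kernel, dilation, rng)
        self.relu2 = ReLU()
        self.drop2 = Dropout(dropout, rng)
        self.downsample = CausalConv1d(c_in, c_out, 1, 1, rng) if c_in != c_out else None
        self.relu_out = ReLU()

    @property
    def layers(self):
        out = [self.conv1, self.conv2]
        if self.downsample is not None:
            out.append(self.downsample)
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = self.drop1.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        y = self.drop2.forward(self.relu2.forward(self.conv2.forward(y, train), train), train)
        res = x if self.downsample is None else self.downsample.forward(x, train)
        return self.relu_out.forward(y + res, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        gy = self.conv2.backward(self.relu2.backward(self.drop2.backward(g)))
        gy = self.conv1.backward(self.relu1.backward(self.drop1.backward(gy)))
        gres = g if self.downsample is None else self.downsample.backward(g)
        return gy + gres


class TCNClassifier(ClassifierModel):
    def __init__(self, hyperparameters: dict) -> None:
        hp = {**DEFAULT_HP, **hyperparameters}
        super().__init__("tcn", hp)
        self.blocks: list[_TemporalBlock] = []
        self.head: Dense | None = None

    @property
    def dilations(self) -> list[int]:
        return [2**i for i in range(self.hyperparameters["n_levels"])]

    @property
    def receptive_field(self) -> int:
        """1 + sum over levels of 2*(kernel-1)*dilation (two convs per block)."""
        k = self.hyperparameters["kernel_size"]
        return 1 + sum(2 * (k - 1) * d for d in self.dilations)

    def _build(self, rng: np.random.Generator) -> None:
        hp = self.hyperparameters
        c = hp["n_filters"]
        self.blocks = []
        c_in = 1
        for d in self.dilations:
            self.blocks.append(
                _TemporalBlock(c_in, c, hp["kernel_size"], d, hp["dropout"], rng)
            )
            c_in = c
        self.head = Dense(c, 3, rng)
        self.head.w *= 0.1  # start near-uniform so early gradients stay sane
        self._last_feat_shape: tuple | None = None

    def conv_activations(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Output of the convolutional stack, (n, filters, 256), pre-pooling.

        Exposed so the causality contract (activations at t depend only on
        inputs <= t) can be verified directly.
        """
        self.ensure_built()
        h = np.asarray(x, dtype=np.float64)[:, None, :]  # (n, 1, t)
        for block in self.blocks:
            h = block.forward(h, train)
        return h

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv_activations(x, train)
        self._last_feat_shape = h.shape
        feat = h.mean(axis=2)  # global average pooling over time
        return self.head.forward(feat, train)

    def _backward(self, grad_logits: np.ndarray) -> None:
        gfeat = self.head.backward(grad_logits)
        t = self._last_feat_shape[2]
        gh = np.broadcast_to(gfeat[:, :, None] / t, self._last_feat_shape).astype(gfeat.dtype)
        gh = np.ascontiguousarray(gh)
        for block in reversed(self.blocks):
            gh = block.backward(gh)

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for block in self.blocks:
            for layer in block.layers:
                out.extend(layer.params)
        out.extend(self.head.params)
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out = []
        for block in self.blocks:
            for layer in block.layers:
                out.extend(layer.grads)
        out.extend(self.head.grads)
        return out


register_architecture("tcn", TCNClassifier)
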