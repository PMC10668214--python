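"""Multilayer-perceptron baseline classifier.

The standard baseline for time-series classification: the 256-sample window
is flattened and passed through fully connected hidden layers.  Temporal
structure is not modeled, which is exactly why it serves as the reference
point for the convolutional architectures.
"""

from __future__ import annotations

import numpy as np

from iedscan.models._nn import Dense, Dropout, ReLU
from iedscan.models.base import ClassifierModel, register_architecture

DEFAULT_HP = {
    "hidden_sizes": [128, 64],
    "dropout": 0.1,
}


class MLPClassifier(ClassifierModel):
    def __init__(self, hyperparameters: dict) -> None:
        hp = {**DEFAULT_HP, **hyperparameters}
        if len(hp["hidden_sizes"]) < 2:
            raise ValueError("MLP baseline requires at least two hidden layers")
        super().__init__("mlp", hp)
        self.layers: list = []

    def _build(self, rng: np.random.Generator) -> None:
        sizes = [256, *self.hyperparameters["hidden_sizes"]]
        drop = self.hyperparameters["dropout"]
        self.layers = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            self.layers.extend([Dense(n_in, n_out, rng), ReLU(), Dropout(drop, rng)])
        self.layers.append(Dense(sizes[-1], 3, rng))

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def _backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


register_architecture("mlp", MLPClassifier)
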