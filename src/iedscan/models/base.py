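"""Model contract and architecture registry for the 3-class EEG classifiers.

Every classifier maps a batch of 1 s single-channel segments (256 samples)
to probability triples over the fixed class order (IED, artifact,
background).  Inputs are standardized per segment (zero mean, unit SD with
the SD floored at 1e-6) so the classifiers are amplitude-scale invariant —
clinical amplitudes vary across sites and montages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable

import numpy as np

CLASS_ORDER: tuple[str, ...] = ("IED", "artifact", "background")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_ORDER)}

SD_FLOOR = 1e-6


class RegistryError(KeyError):
    """Unknown architecture name."""


def standardize_segments(x: np.ndarray) -> np.ndarray:
    """Per-segment standardization: subtract mean, divide by SD (floored).

    Returns float32, the precision the network stack computes in.
    """
    x = np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return ((x - mean) / np.maximum(sd, SD_FLOOR)).astype(np.float32)


class ClassifierModel:
    """Common contract: 256-sample inputs in, normalized 3-class probabilities out."""

    class_order = CLASS_ORDER

    def __init__(self, architecture_name: str, hyperparameters: dict) -> None:
        self.architecture_name = architecture_name
        self.hyperparameters = dict(hyperparameters)
        self.fitted = False
        self._built = False
        self.rng: np.random.Generator | None = None

    # -- to implement in subclasses ------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """Logits (n, 3) from standardized input (n, 256)."""
        raise NotImplementedError

    def _backward(self, grad_logits: np.ndarray) -> None:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        raise NotImplementedError

    @property
    def grads(self) -> list[np.ndarray]:
        raise NotImplementedError

    # -- shared behaviour ----------------------------------------------
    def initialize(self, seed: int) -> None:
        """(Re-)initialize all weights; the seed fully determines them."""
        self.rng = np.random.default_rng(seed)
        self._build(self.rng)
        self._built = True
        self.fitted = False

    def ensure_built(self) -> None:
        if not self._built:
            self.initialize(0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Probability triples for a batch of raw (unstandardized) segments."""
        from iedscan.models._nn import softmax

        self.ensure_built()
        x = standardize_segments(np.atleast_2d(np.asarray(x, dtype=np.float64)))
        out = np.empty((x.shape[0], len(self.class_order)))
        for i in range(0, x.shape[0], batch_size):
            chunk = x[i : i + batch_size]
            out[i : i + chunk.shape[0]] = softmax(self._forward(chunk, train=False))
        return out

    def predict_label(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.class_order)[self.predict_proba(x).argmax(axis=1)]

    # -- checkpointing --------------------------------------------------
    def save(self, path, preprocessing_fingerprint: str = "") -> None:
        """Save weights plus the metadata inference needs to refuse mismatches."""
        self.ensure_built()
        meta = {
            "architecture_name": self.architecture_name,
            "hyperparameters": self.hyperparameters,
            "class_order": list(self.class_order),
            "preprocessing_fingerprint": preprocessing_fingerprint,
            "fitted": self.fitted,
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.params)}
        np.savez(Path(path), meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> tuple["ClassifierModel", dict]:
        """Load any registered architecture from a checkpoint.

        Returns the model and its metadata dict (including the preprocessing
        fingerprint recorded at save time).
        """
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = build_classifier(meta["architecture_name"], meta["hyperparameters"])
            model.initialize(0)
            for i, p in enumerate(model.params):
                stored = data[f"param_{i}"]
                if stored.shape != p.shape:
                    raise ValueError(
                        f"checkpoint parameter {i} shape {stored.shape} != model {p.shape}"
                    )
                p[...] = stored
        model.fitted = bool(meta.get("fitted", True))
        return model, meta


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[[dict], ClassifierModel]] = {}

#: Architectures acknowledged by name but not shipped; a plugin may register them.
PLACEHOLDER_ARCHITECTURES = (
    "fcn", "mlstm_fcn", "resnet", "xresnet1d50",
    "inception_time", "xception_time", "mwdn",
)


def register_architecture(name: str, factory: Callable[[dict], ClassifierModel]) -> None:
    _REGISTRY[name] = factory


def available_architectures() -> list[str]:
    return sorted(_REGISTRY)


def build_classifier(architecture_name: str, hyperparameters: dict | None = None) -> ClassifierModel:
    """Instantiate an unfitted classifier by registry name.

    ``tcn`` and ``mlp`` are shipped; the other architecture names are
    registered as placeholders that raise ``NotImplementedError`` until a
    plugin provides them.
    """
    try:
        factory = _REGISTRY[architecture_name]
    except KeyError:
        raise RegistryError(
            f"unknown architecture {architecture_name!r}; available: "
            f"{available_architectures()}"
        ) from None
    return factory(hyperparameters or {})


def _placeholder(name: str) -> Callable[[dict], ClassifierModel]:
    def factory(_hp: dict) -> ClassifierModel:
        raise NotImplementedError(
            f"architecture {name!r} is a registry placeholder; register a plugin "
            "implementation to use it"
        )

    return factory


for _name in PLACEHOLDER_ARCHITECTURES:
    register_architecture(_name, _placeholder(_name))
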