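"""Shared fixtures: tiny recordings, a deterministic probe model, RNGs."""

from __future__ import annotations

import numpy as np
import pytest

from iedscan.io import CANONICAL_ELECTRODES, EAR_ELECTRODES, SCALP_ELECTRODES, Recording


def make_recording(
    duration_s: float = 10.0,
    fs: float = 256.0,
    values: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    include_ears: bool = True,
) -> Recording:
    """A 19(+2)-channel recording with constant per-electrode values + noise."""
    labels = list(SCALP_ELECTRODES) + (list(EAR_ELECTRODES) if include_ears else [])
    n = int(duration_s * fs)
    sig = np.zeros((len(labels), n))
    if values:
        for name, v in values.items():
            sig[labels.index(name)] += v
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        sig += rng.normal(0, noise_sd, size=sig.shape)
    return Recording(sig, labels, fs, recording_id="fixture")


class ProbeModel:
    """Deterministic stand-in honoring the classifier contract.

    The IED probability is a fixed smooth function of the raw window (its
    peak absolute amplitude), so identical windows always score identically
    and batching cannot change results.
    """

    architecture_name = "probe"
    class_order = ("IED", "artifact", "background")
    fitted = True

    def __init__(self, scale: float = 50.0) -> None:
        self.scale = scale

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        peak = np.abs(x).max(axis=1)
        p_ied = 1.0 / (1.0 + np.exp(-(peak - self.scale) / 5.0))
        rest = 1.0 - p_ied
        return np.stack([p_ied, rest * 0.4, rest * 0.6], axis=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def probe_model() -> ProbeModel:
    return ProbeModel()


@pytest.fixture
def zero_recording() -> Recording:
    return make_recording(duration_s=10.0)
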