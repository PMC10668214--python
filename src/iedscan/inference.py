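"""Stage 1: sliding-window scanning producing 2 x 19 IED-probability frames.

A fitted classifier is run channel-wise over two montage views of a
preprocessed recording with a 1 s window and 0.5 s stride.  Each time
instant (window start) yields one frame: row 0 holds the referential
(earlobe, or common-average for the external-data variant) channels, row 1
the longitudinal-bipolar channels.  The bipolar montage has 18 derivations,
so the 19th bipolar slot is padded with probability 0 — padding can never
create a detection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from iedscan.io import Recording
from iedscan.models.base import CLASS_INDEX, ClassifierModel
from iedscan.montage import MontageView, derive_montage
from iedscan.segmentation import SEGMENT_SAMPLES, n_windows

logger = logging.getLogger(__name__)

N_FRAME_CHANNELS = 19
STRIDE_S = 0.5
WINDOW_S = 1.0


class ContractError(RuntimeError):
    """The model checkpoint's preprocessing fingerprint does not match."""


@dataclass
class ProbabilityFrame:
    """IED probabilities at one instant: (2, 19) = (montage row, channel)."""

    instant: float
    probs: np.ndarray  # (2, 19), values in [0, 1]
    ref_kind: str  # "earlobe" or "common_average"
    ref_channel_names: list[str]
    ref_electrodes: list[frozenset[str]]
    bipolar_channel_names: list[str]
    bipolar_electrodes: list[frozenset[str]]


@dataclass
class FrameSeries:
    """Ordered probability frames over one recording."""

    instants: np.ndarray  # (n_frames,)
    probs: np.ndarray  # (n_frames, 2, 19)
    duration: float
    ref_kind: str
    ref_channel_names: list[str]
    ref_electrodes: list[frozenset[str]]
    bipolar_channel_names: list[str]
    bipolar_electrodes: list[frozenset[str]]
    recording_id: str = ""
    full_probs: np.ndarray | None = None  # optional (n_frames, 2, 19, 3) debug output

    def __len__(self) -> int:
        return len(self.instants)

    def __iter__(self):
        for i in range(len(self)):
            yield self.frame(i)

    def frame(self, i: int) -> ProbabilityFrame:
        return ProbabilityFrame(
            instant=float(self.instants[i]),
            probs=self.probs[i],
            ref_kind=self.ref_kind,
            ref_channel_names=self.ref_channel_names,
            ref_electrodes=self.ref_electrodes,
            bipolar_channel_names=self.bipolar_channel_names,
            bipolar_electrodes=self.bipolar_electrodes,
        )

    # -- serialization (compressed array + JSON sidecar) ----------------
    def save(self, path_prefix) -> None:
        prefix = Path(path_prefix)
        np.savez_compressed(prefix.with_suffix(".npz"), instants=self.instants, probs=self.probs)
        meta = {
            "duration": self.duration,
            "ref_kind": self.ref_kind,
            "ref_channel_names": self.ref_channel_names,
            "ref_electrodes": [sorted(s) for s in self.ref_electrodes],
            "bipolar_channel_names": self.bipolar_channel_names,
            "bipolar_electrodes": [sorted(s) for s in self.bipolar_electrodes],
            "recording_id": self.recording_id,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path_prefix) -> "FrameSeries":
        prefix = Path(path_prefix)
        with np.load(prefix.with_suffix(".npz")) as data:
            instants, probs = data["instants"], data["probs"]
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            instants=instants,
            probs=probs,
            duration=meta["duration"],
            ref_kind=meta["ref_kind"],
            ref_channel_names=meta["ref_channel_names"],
            ref_electrodes=[frozenset(s) for s in meta["ref_electrodes"]],
            bipolar_channel_names=meta["bipolar_channel_names"],
            bipolar_electrodes=[frozenset(s) for s in meta["bipolar_electrodes"]],
            recording_id=meta["recording_id"],
        )


def _window_starts(duration: float) -> np.ndarray:
    if duration < WINDOW_S:
        return np.array([])
    return np.arange(n_windows(duration)) * STRIDE_S


def _scan_view(view: MontageView, model: ClassifierModel, starts_idx: np.ndarray) -> np.ndarray:
    """All-class probabilities (n_frames, n_channels, 3) for one montage view."""
    n_frames = len(starts_idx)
    out = np.empty((n_frames, view.n_channels, 3))
    for ch in range(view.n_channels):
        sig = view.channel_signals[ch]
        windows = np.lib.stride_tricks.sliding_window_view(sig, SEGMENT_SAMPLES)[starts_idx]
        out[:, ch, :] = model.predict_proba(windows)
    return out


def scan_recording(
    recording: Recording,
    model: ClassifierModel,
    ref_montage: str = "earlobe",
    expected_fingerprint: str | None = None,
    model_fingerprint: str | None = None,
    keep_all_classes: bool = False,
) -> FrameSeries:
    """Run the classifier over both montages with a 1 s window, 0.5 s stride.

    The recording must already be preprocessed (256 Hz, filter chain); when
    both fingerprints are given they must agree, otherwise a
    :class:`ContractError` is raised.  Recordings shorter than one window
    yield an empty series with a warning.
    """
    if expected_fingerprint is not None and model_fingerprint is not None:
        if expected_fingerprint != model_fingerprint:
            raise ContractError(
                f"preprocessing fingerprint mismatch: recording {expected_fingerprint!r}"
                f" vs checkpoint {model_fingerprint!r}"
            )
    if not model.fitted:
        warnings.warn("scanning with an unfitted model", stacklevel=2)

    ref = derive_montage(recording, ref_montage)
    bip = derive_montage(recording, "bipolar")
    duration = recording.duration
    starts = _window_starts(duration)
    if len(starts) == 0:
        warnings.warn(
            f"recording shorter than {WINDOW_S} s; empty frame series", stacklevel=2
        )
        probs = np.zeros((0, 2, N_FRAME_CHANNELS))
        full = np.zeros((0, 2, N_FRAME_CHANNELS, 3)) if keep_all_classes else None
        return FrameSeries(
            instants=starts,
            probs=probs,
            duration=duration,
            ref_kind=ref_montage,
            ref_channel_names=ref.channel_names,
            ref_electrodes=ref.electrodes_per_channel,
            bipolar_channel_names=bip.channel_names,
            bipolar_electrodes=bip.electrodes_per_channel,
            recording_id=recording.recording_id,
            full_probs=full,
        )

    starts_idx = np.round(starts * recording.sampling_rate).astype(int)
    ref_all = _scan_view(ref, model, starts_idx)
    bip_all = _scan_view(bip, model, starts_idx)

    n_frames = len(starts)
    probs = np.zeros((n_frames, 2, N_FRAME_CHANNELS))
    ied = CLASS_INDEX["IED"]
    probs[:, 0, : ref.n_channels] = ref_all[:, :, ied]
    probs[:, 1, : bip.n_channels] = bip_all[:, :, ied]  # slot 19 stays 0 (padding)

    full = None
    if keep_all_classes:
        full = np.zeros((n_frames, 2, N_FRAME_CHANNELS, 3))
        full[:, 0, : ref.n_channels] = ref_all
        full[:, 1, : bip.n_channels] = bip_all

    return FrameSeries(
        instants=starts,
        probs=probs,
        duration=duration,
        ref_kind=ref_montage,
        ref_channel_names=ref.channel_names,
        ref_electrodes=ref.electrodes_per_channel,
        bipolar_channel_names=bip.channel_names,
        bipolar_electrodes=bip.electrodes_per_channel,
        recording_id=recording.recording_id,
        full_probs=full,
    )
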