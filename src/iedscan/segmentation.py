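"""From channel-wise annotations to the labeled 1 s training-segment dataset.

Annotations of duration >= 1 s are divided into consecutive 1 s windows with
0.5 s overlap; shorter annotations (typically single IED waveforms) yield one
1 s window centered on the annotation midpoint, shifted inward (never
zero-padded) when it would cross a recording boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from iedscan.io import LABELS, Annotation, ValidationError
from iedscan.montage import MontageView

SEGMENT_LEN_S = 1.0
SEGMENT_STRIDE_S = 0.5
SEGMENT_SAMPLES = 256


class DataError(ValueError):
    """Dataset composition violates an operation's precondition."""


@dataclass(frozen=True)
class Segment:
    """One 1 s single-channel window (256 samples at 256 Hz) with its label."""

    samples: np.ndarray
    label: str
    source: tuple  # (recording_id, montage_kind, channel, start_s)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.shape != (SEGMENT_SAMPLES,):
            raise ValidationError(
                f"segment must have exactly {SEGMENT_SAMPLES} samples, got {self.samples.shape}"
            )
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")


@dataclass
class FoldAssignment:
    """Fold index in ``[0, k)`` for every segment of a dataset."""

    fold_index: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def n_windows(duration_s: float) -> int:
    """Number of 1 s / 0.5 s-stride windows covering an interval of ``duration_s`` >= 1."""
    return int(np.floor((duration_s - SEGMENT_LEN_S) / SEGMENT_STRIDE_S + 1e-9)) + 1


def segment_annotation(
    annotation: Annotation,
    view: MontageView,
    sampling_rate: float = 256.0,
    recording_id: str = "",
) -> list[Segment]:
    """Cut one annotation into labeled 1 s segments on its montage channel.

    Raises :class:`ValidationError` when the annotation lies outside the
    recording extent, and :class:`KeyError` when its channel is absent from
    the view.
    """
    if annotation.channel not in view.channel_names:
        raise KeyError(
            f"channel {annotation.channel!r} not in {view.kind} montage view"
        )
    sig = view.channel(annotation.channel)
    total_s = sig.shape[0] / sampling_rate
    if annotation.start < 0 or annotation.end > total_s + 1e-9:
        raise ValidationError(
            f"annotation [{annotation.start}, {annotation.end}) outside recording "
            f"extent [0, {total_s:.3f})"
        )

    dur = annotation.duration
    starts: list[float]
    if dur >= SEGMENT_LEN_S - 1e-9:
        starts = [
            annotation.start + k * SEGMENT_STRIDE_S for k in range(n_windows(dur))
        ]
    else:
        mid = 0.5 * (annotation.start + annotation.end)
        start = mid - SEGMENT_LEN_S / 2.0
        # shift inward at recording edges; never zero-pad
        start = min(max(start, 0.0), total_s - SEGMENT_LEN_S)
        if start < 0:
            raise ValidationError("recording shorter than one segment window")
        starts = [start]

    win = SEGMENT_SAMPLES
    out = []
    for s in starts:
        i0 = int(round(s * sampling_rate))
        i0 = min(i0, sig.shape[0] - win)
        out.append(
            Segment(
                samples=sig[i0 : i0 + win].copy(),
                label=annotation.label,
                source=(recording_id, view.kind, annotation.channel, i0 / sampling_rate),
            )
        )
    return out


def balance_classes(segments: list[Segment], seed: int) -> list[Segment]:
    """Oversample minority classes with replacement to the majority count.

    Every input segment is retained (the output is a multiset superset of the
    input); the result is deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[int]] = {lbl: [] for lbl in LABELS}
    for i, seg in enumerate(segments):
        by_label[seg.label].append(i)
    for lbl, idxs in by_label.items():
        if not idxs:
            raise DataError(f"class {lbl!r} has no segments")
    target = max(len(idxs) for idxs in by_label.values())
    out_indices: list[int] = []
    for lbl in LABELS:
        idxs = by_label[lbl]
        out_indices.extend(idxs)
        deficit = target - len(idxs)
        if deficit > 0:
            out_indices.extend(rng.choice(idxs, size=deficit, replace=True).tolist())
    rng.shuffle(out_indices)
    return [segments[i] for i in out_indices]


def stratified_folds(segments: list[Segment], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Assign segments to ``k`` folds stratified on (label, montage kind).

    Each fold's share of every (label, montage) stratum stays within 2
    percentage points of the stratum's global share.  Raises
    :class:`DataError` when a stratum has fewer than ``k`` members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    strata = np.array([f"{seg.label}|{seg.source[1]}" for seg in segments])
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < k:
        small = np.unique(strata)[counts.argmin()]
        raise DataError(f"stratum {small!r} has fewer than k={k} segments")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(len(segments), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(segments)), strata)):
        fold_index[test_idx] = fold
    return FoldAssignment(fold_index=fold_index, k=k)
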