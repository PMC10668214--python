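"""EDF recordings and the plain-text annotation/event interval formats.

All times are seconds from recording start and all intervals are half-open
``[start, end)``.  Signals are kept in microvolts throughout the package.

Two CSV dialects are defined here:

* **annotations** — channel-wise training labels, one row per interval, with
  header ``kind,montage,channel,label,start_s,end_s`` where ``kind`` is the
  literal ``annotation``, ``montage`` is ``earlobe`` or ``bipolar`` and
  ``label`` is one of ``IED``, ``artifact``, ``background``.
* **events** — recording-wise IED event reference labels with header
  ``start_s,end_s``.  Event lists are merged on read: consecutive events whose
  gap is < 1 s are treated as a single event.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: The 19 scalp electrodes of the reduced 10-20 montage, in conventional order.
SCALP_ELECTRODES: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Earlobe reference electrodes.
EAR_ELECTRODES: tuple[str, ...] = ("A1", "A2")

CANONICAL_ELECTRODES: tuple[str, ...] = SCALP_ELECTRODES + EAR_ELECTRODES

LABELS: tuple[str, ...] = ("IED", "artifact", "background")
MONTAGE_KINDS: tuple[str, ...] = ("earlobe", "bipolar", "common_average")

#: Minimum gap between distinct IED events; closer events are merged into one.
EVENT_MERGE_GAP_S: float = 1.0

_CANONICAL_BY_UPPER = {name.upper(): name for name in CANONICAL_ELECTRODES}
_REFERENCE_SUFFIXES = ("REF", "LE", "A1", "A2", "AVG", "AV", "M1", "M2")


class FormatError(ValueError):
    """A file or label does not conform to the expected format."""


class ValidationError(ValueError):
    """An interval or label fails a type invariant."""


@dataclass
class Recording:
    """Multichannel raw EEG with electrode labels, in microvolts.

    Invariants: all signals share one length, ``sampling_rate > 0`` and
    electrode labels are unique.
    """

    signals: np.ndarray  # (n_channels, n_samples) float64, microvolts
    electrode_labels: list[str]
    sampling_rate: float
    start_time: float = 0.0
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValidationError("signals must be a 2-D (channels x samples) array")
        if len(self.electrode_labels) != self.signals.shape[0]:
            raise ValidationError(
                f"{len(self.electrode_labels)} labels for {self.signals.shape[0]} signal rows"
            )
        if len(set(self.electrode_labels)) != len(self.electrode_labels):
            raise ValidationError("electrode labels must be unique")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the signal of one electrode by canonical label."""
        try:
            idx = self.electrode_labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in recording") from None
        return self.signals[idx]

    def has_electrodes(self, labels) -> bool:
        return set(labels).issubset(self.electrode_labels)


@dataclass(frozen=True)
class Annotation:
    """A channel-wise labeled interval used for classifier training."""

    montage_kind: str
    channel: str
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.montage_kind not in MONTAGE_KINDS:
            raise ValidationError(f"unknown montage kind {self.montage_kind!r}")
        if self.label not in LABELS:
            raise ValidationError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )
        if not self.end > self.start:
            raise ValidationError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class EventLabel:
    """A time-wise IED event interval used for event-level evaluation."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


def merge_events(events, min_gap: float = EVENT_MERGE_GAP_S) -> list[EventLabel]:
    """Merge event intervals whose gap is smaller than ``min_gap`` seconds.

    Merging is transitive: a chain of events each closer than ``min_gap`` to
    the next collapses into one.  The result is sorted, non-overlapping and
    idempotent under re-merging.
    """
    if not events:
        return []
    ordered = sorted(events)
    merged: list[EventLabel] = [ordered[0]]
    for ev in ordered[1:]:
        last = merged[-1]
        if ev.start - last.end < min_gap:
            merged[-1] = EventLabel(last.start, max(last.end, ev.end))
        else:
            merged.append(ev)
    return merged


# ---------------------------------------------------------------------------
# Electrode label normalization
# ---------------------------------------------------------------------------

def normalize_label(raw: str) -> str | None:
    """Map a vendor channel label to its canonical 10-20 name.

    Strips an ``EEG `` prefix and a reference suffix (``-Ref``, ``-LE``,
    ``-A1``/``-A2``, ``-AVG``) and matches case-insensitively against the
    canonical electrode set.  Returns ``None`` when no canonical electrode
    matches.

    >>> normalize_label("EEG FP1-A1")
    'Fp1'
    """
    name = raw.strip()
    if name.upper().startswith("EEG "):
        name = name[4:].strip()
    if "-" in name:
        stem, _, suffix = name.rpartition("-")
        if suffix.strip().upper() in _REFERENCE_SUFFIXES and stem.strip():
            name = stem.strip()
    return _CANONICAL_BY_UPPER.get(name.upper())


# ---------------------------------------------------------------------------
# EDF reading / writing
# ---------------------------------------------------------------------------

def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    Channel labels are normalized to canonical 10-20 names; labels that match
    no canonical electrode are carried through unchanged with a warning (they
    are excluded later at montage derivation).

    Raises :class:`FormatError` when no recognizable 10-20 labels are present,
    and :class:`OSError` when the file is missing or unreadable.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of ValueError/OSError subtypes
        raise OSError(f"cannot read EDF file {path}: {exc}") from exc

    if len(raw.ch_names) == 0:
        raise FormatError(f"{path} contains no channels")

    labels: list[str] = []
    unmatched: list[str] = []
    for ch in raw.ch_names:
        canonical = normalize_label(ch)
        if canonical is None:
            unmatched.append(ch)
            labels.append(ch)
        else:
            labels.append(canonical)
    if not any(lbl in CANONICAL_ELECTRODES for lbl in labels):
        raise FormatError(
            f"{path} has no recognizable 10-20 electrode labels; found {raw.ch_names}"
        )
    if unmatched:
        logger.warning("non-10-20 channel labels carried through: %s", unmatched)
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path} has duplicate electrode labels after normalization")

    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        signals=data_uv,
        electrode_labels=labels,
        sampling_rate=float(raw.info["sfreq"]),
        recording_id=path.stem,
    )


def write_edf(recording: Recording, path) -> None:
    """Write a :class:`Recording` to a minimal EDF file.

    Samples are quantized to EDF's 16-bit integer range per channel; the
    round trip through :func:`read_edf` preserves values to quantization
    accuracy and labels exactly.  The record duration is chosen so the
    samples-per-record count is integral.
    """
    path = Path(path)
    n_ch = len(recording.electrode_labels)
    if n_ch == 0:
        raise FormatError("cannot write an EDF file with zero channels")
    fs = recording.sampling_rate
    if abs(fs - round(fs)) < 1e-9:
        record_dur = 1.0
        spr = int(round(fs))
    else:  # fall back to a single data record holding everything
        record_dur = recording.duration
        spr = recording.n_samples

    n_samples = recording.n_samples
    n_records = int(np.ceil(n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samples] = recording.signals

    phys_min = np.floor(padded.min(axis=1))
    phys_max = np.ceil(padded.max(axis=1))
    # keep a non-degenerate physical range for flat channels
    flat = phys_max - phys_min < 1.0
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            pad("0", 8),
            pad(recording.recording_id or "X X X X", 80),
            pad("Synthetic EDF", 80),
            pad(now.strftime("%d.%m.%y"), 8),
            pad(now.strftime("%H.%M.%S"), 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad(f"{record_dur:g}", 8),
            pad(str(n_ch), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(pad(lbl, 16) for lbl in recording.electrode_labels),
            b"".join(pad("", 80) for _ in range(n_ch)),
            b"".join(pad("uV", 8) for _ in range(n_ch)),
            b"".join(pad(f"{phys_min[i]:g}", 8) for i in range(n_ch)),
            b"".join(pad(f"{phys_max[i]:g}", 8) for i in range(n_ch)),
            b"".join(pad(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(pad(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(pad("", 80) for _ in range(n_ch)),
            b"".join(pad(str(spr), 8) for _ in range(n_ch)),
            b"".join(pad("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            block = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# CSV annotation / event files
# ---------------------------------------------------------------------------

_ANNOTATION_HEADER = ["kind", "montage", "channel", "label", "start_s", "end_s"]
_EVENT_HEADER = ["start_s", "end_s"]


def read_annotations(path) -> list[Annotation]:
    """Read channel-wise training annotations from CSV.

    Raises :class:`ValidationError` naming the offending row on bad intervals
    or unknown labels.
    """
    path = Path(path)
    out: list[Annotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _ANNOTATION_HEADER:
            raise FormatError(
                f"{path}: expected header {_ANNOTATION_HEADER}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    Annotation(
                        montage_kind=row["montage"],
                        channel=row["channel"],
                        label=row["label"],
                        start=float(row["start_s"]),
                        end=float(row["end_s"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
    return out


def write_annotations(annotations, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_HEADER)
        for ann in annotations:
            writer.writerow(
                [
                    "annotation",
                    ann.montage_kind,
                    ann.channel,
                    ann.label,
                    f"{ann.start:.3f}",
                    f"{ann.end:.3f}",
                ]
            )


def read_events(path) -> list[EventLabel]:
    """Read IED event labels from CSV and apply the < 1 s merging rule."""
    path = Path(path)
    events: list[EventLabel] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _EVENT_HEADER:
            raise FormatError(
                f"{path}: expected header {_EVENT_HEADER}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                events.append(EventLabel(float(row["start_s"]), float(row["end_s"])))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
    return merge_events(events)


def write_events(events, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_HEADER)
        for ev in events:
            writer.writerow([f"{ev.start:.3f}", f"{ev.end:.3f}"])
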