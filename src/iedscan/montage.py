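"""Montage derivations with per-channel electrode provenance.

Three views are supported:

* ``earlobe`` — referential: left-hemisphere electrodes referenced to A1,
  right to A2, midline (Fz, Cz, Pz) to (A1+A2)/2.  Preserves waveform shape
  and amplitude.
* ``bipolar`` — the standard longitudinal ("double banana") chains of 18
  anterior-to-posterior derivations.  Suppresses common-mode activity and
  highlights local gradients.
* ``common_average`` — each scalp electrode minus the mean of all 19.

Channel order is part of the system contract (probability frames are
index-aligned), so the orders defined here are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from iedscan.io import EAR_ELECTRODES, SCALP_ELECTRODES, Recording

#: Longitudinal bipolar derivations in conventional temporal-then-parasagittal order.
BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)

LEFT_ELECTRODES = frozenset({"Fp1", "F3", "C3", "P3", "O1", "F7", "T3", "T5"})
RIGHT_ELECTRODES = frozenset({"Fp2", "F4", "C4", "P4", "O2", "F8", "T4", "T6"})
MIDLINE_ELECTRODES = frozenset({"Fz", "Cz", "Pz"})


class MontageError(ValueError):
    """A required electrode is missing or the montage kind is unknown."""


@dataclass
class MontageView:
    """Derived channels plus, per channel, the scalp electrodes it involves."""

    kind: str
    channel_names: list[str]
    channel_signals: np.ndarray  # (n_channels, n_samples)
    electrodes_per_channel: list[frozenset[str]]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel(self, name: str) -> np.ndarray:
        return self.channel_signals[self.channel_names.index(name)]


def electrodes_of(view: MontageView, channel_index: int) -> frozenset[str]:
    """Scalp electrodes contributing to one derived channel.

    Referential and common-average channels map to the singleton scalp
    electrode (reference electrodes excluded); bipolar channels map to their
    two-electrode pair.
    """
    if not 0 <= channel_index < view.n_channels:
        raise IndexError(
            f"channel index {channel_index} out of range for {view.n_channels} channels"
        )
    return view.electrodes_per_channel[channel_index]


def derive_montage(recording: Recording, kind: str) -> MontageView:
    """Derive a montage view from a recording containing the 19 scalp electrodes.

    The earlobe kind additionally requires A1 and A2.  Raises
    :class:`MontageError` naming any missing electrode.
    """
    missing = [e for e in SCALP_ELECTRODES if e not in recording.electrode_labels]
    if missing:
        raise MontageError(f"recording lacks scalp electrode(s): {', '.join(missing)}")

    if kind == "earlobe":
        for ref in EAR_ELECTRODES:
            if ref not in recording.electrode_labels:
                raise MontageError(f"earlobe montage requires electrode {ref}")
        a1 = recording.channel("A1")
        a2 = recording.channel("A2")
        linked = 0.5 * (a1 + a2)
        rows, names, provenance = [], [], []
        for e in SCALP_ELECTRODES:
            if e in LEFT_ELECTRODES:
                ref_sig = a1
            elif e in RIGHT_ELECTRODES:
                ref_sig = a2
            else:  # midline
                ref_sig = linked
            rows.append(recording.channel(e) - ref_sig)
            names.append(e)
            provenance.append(frozenset({e}))
        return MontageView(kind, names, np.array(rows), provenance)

    if kind == "bipolar":
        rows, names, provenance = [], [], []
        for a, b in BIPOLAR_PAIRS:
            rows.append(recording.channel(a) - recording.channel(b))
            names.append(f"{a}-{b}")
            provenance.append(frozenset({a, b}))
        return MontageView(kind, names, np.array(rows), provenance)

    if kind == "common_average":
        scalp = np.array([recording.channel(e) for e in SCALP_ELECTRODES])
        avg = scalp.mean(axis=0)
        return MontageView(
            kind,
            list(SCALP_ELECTRODES),
            scalp - avg,
            [frozenset({e}) for e in SCALP_ELECTRODES],
        )

    raise MontageError(f"unknown montage kind {kind!r}")
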