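"""Stage 2: from probability frames to IED events.

The two-montage decision mechanism (TMDM) mirrors clinical reading across
montages.  An instant is positive when

1. at least one referential-montage probability and at least two
   bipolar-montage probabilities reach the threshold, and
2. the activations correlate spatially: some active referential channel's
   electrode belongs to some active bipolar channel's electrode pair.

The single-montage mechanism (SMDM) uses only the maximum referential
probability.  The common-average variant applies the TMDM rule with the
referential row computed from the common-average montage (and skips the
spatial condition when no bipolar row is available).

"Reaches the threshold" is inclusive (>=), so a threshold of 1.0 remains
meaningful for perfectly confident outputs.  Maximal runs of positive
instants become provisional events spanning the union of their 1 s windows;
events closer than 1 s are merged transitively, matching the reference-label
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from iedscan.inference import FrameSeries, ProbabilityFrame, WINDOW_S
from iedscan.io import EVENT_MERGE_GAP_S

MODES = ("TMDM", "SMDM", "common_average")

#: Spatial-correlation rule variants; "overlap" is the weakest faithful
#: reading (non-empty electrode intersection), "strict" demands one
#: referential electrode contained in >= 2 active bipolar pairs (a
#: phase-reversal-like footprint).
SPATIAL_RULES = ("overlap", "strict")


@dataclass(frozen=True)
class InstantDecision:
    instant: float
    positive: bool
    active_ref: frozenset[int]
    active_bipolar: frozenset[int]


@dataclass(frozen=True)
class Detection:
    """A detected IED event interval."""

    start: float
    end: float
    peak_probability: float
    channels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def decide_instant(
    frame: ProbabilityFrame,
    threshold: float,
    mode: str = "TMDM",
    spatial_rule: str = "overlap",
) -> InstantDecision:
    """Apply one decision mechanism to a single 2 x 19 probability frame."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if spatial_rule not in SPATIAL_RULES:
        raise ValueError(f"unknown spatial rule {spatial_rule!r}")

    n_ref = len(frame.ref_channel_names)
    n_bip = len(frame.bipolar_channel_names)
    active_ref = frozenset(
        i for i in range(n_ref) if frame.probs[0, i] >= threshold
    )
    active_bip = frozenset(
        i for i in range(n_bip) if frame.probs[1, i] >= threshold
    )

    if mode == "SMDM":
        positive = len(active_ref) > 0
        return InstantDecision(frame.instant, positive, active_ref, active_bip)

    # TMDM / common_average: condition 1 — montage-wise activation counts
    if mode == "common_average" and n_bip == 0:
        positive = len(active_ref) >= 1
        return InstantDecision(frame.instant, positive, active_ref, active_bip)

    if len(active_ref) < 1 or len(active_bip) < 2:
        return InstantDecision(frame.instant, False, active_ref, active_bip)

    # condition 2 — spatial correlation between montages
    bip_sets = [frame.bipolar_electrodes[j] for j in active_bip]
    if spatial_rule == "overlap":
        positive = any(
            frame.ref_electrodes[i] & pair for i in active_ref for pair in bip_sets
        )
    else:  # strict: one referential electrode in >= 2 active bipolar pairs
        positive = any(
            sum(1 for pair in bip_sets if frame.ref_electrodes[i] & pair) >= 2
            for i in active_ref
        )
    return InstantDecision(frame.instant, positive, active_ref, active_bip)


def decide_series(
    series: FrameSeries,
    threshold: float,
    mode: str = "TMDM",
    spatial_rule: str = "overlap",
) -> list[InstantDecision]:
    return [
        decide_instant(frame, threshold, mode, spatial_rule) for frame in series
    ]


def form_events(
    decisions: list[InstantDecision],
    series: FrameSeries,
    min_gap: float = EVENT_MERGE_GAP_S,
) -> list[Detection]:
    """Merge positive instants into detections.

    Each maximal run of positive instants spans the union of its 1 s windows,
    ``[first instant, last instant + 1 s)``; provisional events with gaps
    below ``min_gap`` are merged transitively.  Peak probability and the
    active channel set are aggregated over merged constituents.
    """
    if len(decisions) != len(series):
        raise ValueError("decisions must align one-to-one with frames")

    provisional: list[Detection] = []
    run: list[tuple[InstantDecision, ProbabilityFrame]] = []

    def flush() -> None:
        if not run:
            return
        start = run[0][0].instant
        end = run[-1][0].instant + WINDOW_S
        peak = 0.0
        channels: set[str] = set()
        for dec, frame in run:
            for i in dec.active_ref:
                peak = max(peak, float(frame.probs[0, i]))
                channels.add(frame.ref_channel_names[i])
            for j in dec.active_bipolar:
                peak = max(peak, float(frame.probs[1, j]))
                channels.add(frame.bipolar_channel_names[j])
        provisional.append(Detection(start, end, peak, frozenset(channels)))
        run.clear()

    for dec, frame in zip(decisions, series):
        if dec.positive:
            run.append((dec, frame))
        else:
            flush()
    flush()

    merged: list[Detection] = []
    for det in provisional:
        if merged and det.start - merged[-1].end < min_gap:
            last = merged[-1]
            merged[-1] = Detection(
                last.start,
                max(last.end, det.end),
                max(last.peak_probability, det.peak_probability),
                last.channels | det.channels,
            )
        else:
            merged.append(det)
    return merged


def detect_events(
    series: FrameSeries,
    threshold: float,
    mode: str = "TMDM",
    spatial_rule: str = "overlap",
) -> list[Detection]:
    """Convenience: decide every instant, then form merged events."""
    return form_events(decide_series(series, threshold, mode, spatial_rule), series)
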