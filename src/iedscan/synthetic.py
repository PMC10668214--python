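"""Reproducible synthetic scalp EEG with ground-truth annotations.

The generator emulates the statistical structure the detector assumes, not
biophysical reality:

* background — 1/f ("pink") noise on every electrode plus a 10 Hz alpha
  rhythm on posterior electrodes (O1, O2, P3, P4) with a slow amplitude
  envelope;
* IED events — a biphasic spike (~70 ms) followed by a slow wave (~300 ms),
  injected at the electrode level through a focal spatial field (gain 1 at a
  focus electrode, decaying by a factor per neighbor step on the 10-20
  adjacency graph), so montage derivation produces physically consistent
  earlobe and bipolar appearances;
* artifacts — EMG (30-90 Hz bursts on temporal electrodes), ECG (a ~1.1 Hz
  QRS-like train on temporal electrodes) and movement (<2 Hz high-amplitude
  excursions).

Event timing: events arrive at a Poisson-like rate (one Bernoulli draw per
1 s epoch), midpoints are aligned to epoch centers with a small jitter, and
arrivals are thinned so consecutive events keep a configurable minimum gap
(default 3 s).  Epoch alignment keeps epoch-level agreement scoring exact in
oracle validation and does not affect the sliding-window detector, which
scans every 0.5 s regardless.

A1/A2 carry attenuated background only, so the earlobe reference is quiet.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import signal as sps

from iedscan.inference import N_FRAME_CHANNELS, FrameSeries
from iedscan.io import (
    EAR_ELECTRODES,
    SCALP_ELECTRODES,
    Annotation,
    EventLabel,
    Recording,
    merge_events,
)
from iedscan.montage import BIPOLAR_PAIRS
from iedscan.segmentation import SEGMENT_SAMPLES, Segment

#: 10-20 scalp adjacency used for the focal spatial field.
ADJACENCY: dict[str, tuple[str, ...]] = {
    "Fp1": ("F7", "F3", "Fp2", "Fz"),
    "Fp2": ("F8", "F4", "Fp1", "Fz"),
    "F7": ("Fp1", "F3", "T3"),
    "F8": ("Fp2", "F4", "T4"),
    "F3": ("Fp1", "F7", "C3", "Fz"),
    "F4": ("Fp2", "F8", "C4", "Fz"),
    "T3": ("F7", "C3", "T5"),
    "T4": ("F8", "C4", "T6"),
    "C3": ("F3", "T3", "P3", "Cz"),
    "C4": ("F4", "T4", "P4", "Cz"),
    "T5": ("T3", "P3", "O1"),
    "T6": ("T4", "P4", "O2"),
    "P3": ("C3", "T5", "O1", "Pz"),
    "P4": ("C4", "T6", "O2", "Pz"),
    "O1": ("T5", "P3", "O2"),
    "O2": ("T6", "P4", "O1"),
    "Fz": ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "Pz": ("Cz", "P3", "P4"),
}

POSTERIOR_ELECTRODES = ("O1", "O2", "P3", "P4")
TEMPORAL_ELECTRODES = ("F7", "F8", "T3", "T4", "T5", "T6")

#: Electrodes appearing in >= 2 longitudinal-bipolar derivations; default IED
#: foci are drawn from these so every event can present on two bipolar
#: channels, as the two-montage decision rule requires.
_counts: dict[str, int] = {}
for _a, _b in BIPOLAR_PAIRS:
    _counts[_a] = _counts.get(_a, 0) + 1
    _counts[_b] = _counts.get(_b, 0) + 1
FOCUS_ELECTRODES: tuple[str, ...] = tuple(
    e for e in SCALP_ELECTRODES if _counts.get(e, 0) >= 2
)

SPIKE_DUR_S = 0.07
WAVE_DUR_S = 0.30
EVENT_DUR_S = SPIKE_DUR_S + WAVE_DUR_S


class ConfigError(ValueError):
    """Simulation configuration cannot be satisfied."""


@dataclass
class SimConfig:
    duration_s: float = 600.0
    sampling_rate: float = 256.0
    seed: int = 0
    ied_rate_per_min: float = 2.0
    ied_amplitude_uv: float = 120.0
    ied_field: dict[str, float] | None = None  # None: random focal field per event
    field_decay: float = 0.5
    artifact_rates: dict[str, float] = dc_field(
        default_factory=lambda: {"EMG": 1.0, "ECG": 0.5, "movement": 0.5}
    )
    alpha_amplitude_uv: float = 30.0
    pink_noise_scale: float = 10.0
    min_event_gap_s: float = 3.0
    event_jitter_s: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_s < 10:
            raise ConfigError("duration_s must be at least 10 s")
        if self.ied_rate_per_min < 0 or any(r < 0 for r in self.artifact_rates.values()):
            raise ConfigError("rates must be non-negative")
        if self.ied_field is not None:
            gains = np.array(list(self.ied_field.values()))
            if gains.min() < 0 or gains.max() > 1 or not np.isclose(gains.max(), 1.0):
                raise ConfigError("field gains must lie in [0, 1] with max = 1")
        expected = self.ied_rate_per_min * self.duration_s / 60.0
        capacity = self.duration_s / (self.min_event_gap_s + EVENT_DUR_S)
        if expected > capacity:
            raise ConfigError(
                f"expected {expected:.0f} events exceed capacity {capacity:.0f} "
                "under the minimum-gap rule"
            )


@dataclass
class GroundTruth:
    events: list[EventLabel]
    annotations: list[Annotation]


# ---------------------------------------------------------------------------
# Waveform building blocks
# ---------------------------------------------------------------------------

def spike_wave_template(fs: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """Negative biphasic spike (difference of Gaussians) + half-sine slow wave.

    Peak absolute amplitude is normalized to 1; total length ~0.37 s.
    Morphology jitters slightly when an rng is given.
    """
    j = (lambda lo, hi: rng.uniform(lo, hi)) if rng is not None else (lambda lo, hi: (lo + hi) / 2)
    spike_w = j(0.8, 1.2)
    n_spike = int(SPIKE_DUR_S * fs)
    t = np.arange(n_spike) / fs
    c = SPIKE_DUR_S / 2
    s1 = np.exp(-0.5 * ((t - c) / (0.008 * spike_w)) ** 2)
    s2 = np.exp(-0.5 * ((t - c - 0.018) / (0.014 * spike_w)) ** 2)
    spike = -(s1 - 0.6 * s2)

    n_wave = int(WAVE_DUR_S * fs)
    wave = -j(0.4, 0.7) * np.sin(np.pi * np.arange(n_wave) / n_wave)

    out = np.concatenate([spike, wave])
    return out / np.abs(out).max()


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / (sd if sd > 0 else 1.0)


def _alpha_rhythm(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """10 Hz rhythm with a slow random amplitude envelope, unit peak scale."""
    t = np.arange(n) / fs
    envelope = 0.5 + 0.5 * np.abs(pink_noise(n, rng))
    envelope = sps.savgol_filter(envelope, min(int(fs) | 1, n - (n + 1) % 2), 3) if n > int(fs) else envelope
    envelope = np.clip(envelope, 0.0, 1.5)
    return envelope * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))


def _emg_burst(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    sos = sps.butter(4, [30 / (fs / 2), 90 / (fs / 2)], btype="bandpass", output="sos")
    burst = sps.sosfilt(sos, noise)
    burst *= np.hanning(n)
    peak = np.abs(burst).max()
    return burst / (peak if peak > 0 else 1.0)


def _ecg_train(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """QRS-like biphasic spikelets at ~1.1 Hz, unit peak."""
    out = np.zeros(n)
    qrs_n = int(0.08 * fs)
    t = np.arange(qrs_n) / fs
    qrs = np.sin(2 * np.pi * t / 0.08) * np.hanning(qrs_n)
    period = 1.0 / rng.uniform(0.9, 1.3)
    pos = rng.uniform(0, 0.2)
    while int(pos * fs) + qrs_n < n:
        i0 = int(pos * fs)
        out[i0 : i0 + qrs_n] += qrs
        pos += period
    peak = np.abs(out).max()
    return out / (peak if peak > 0 else 1.0)


def _movement_excursion(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Sub-2 Hz high-amplitude baseline excursion, unit peak."""
    t = np.arange(n) / fs
    f = rng.uniform(0.3, 1.5)
    out = np.sin(np.pi * np.arange(n) / n) * np.sin(2 * np.pi * f * t + rng.uniform(0, np.pi))
    peak = np.abs(out).max()
    return out / (peak if peak > 0 else 1.0)


def focal_field(center: str, decay: float = 0.5) -> dict[str, float]:
    """Gain map: 1 at the focus, ``decay``^d at graph distance d, cut at d=2."""
    gains = {center: 1.0}
    frontier = {center}
    for d in (1, 2):
        nxt: set[str] = set()
        for e in frontier:
            for nb in ADJACENCY[e]:
                if nb not in gains:
                    gains[nb] = decay**d
                    nxt.add(nb)
        frontier = nxt
    return gains


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------

def _place_events(config: SimConfig, rng: np.random.Generator) -> list[float]:
    """Event midpoints: Bernoulli per epoch, epoch-center aligned with jitter,
    thinned to the minimum gap."""
    p = config.ied_rate_per_min / 60.0
    n_epochs = int(config.duration_s)
    lo = 2
    hi = n_epochs - 2
    mids = []
    draws = rng.random(n_epochs)
    jitters = rng.uniform(-config.event_jitter_s, config.event_jitter_s, n_epochs)
    for k in range(lo, hi):
        if draws[k] < p:
            mids.append(k + 0.5 + jitters[k])
    kept: list[float] = []
    for m in mids:  # thinning drops the later event of a close pair
        if kept and (m - EVENT_DUR_S / 2) - (kept[-1] + EVENT_DUR_S / 2) < config.min_event_gap_s:
            continue
        kept.append(m)
    return kept


def _inject(signals: dict[str, np.ndarray], template: np.ndarray,
            gains: dict[str, float], start_idx: int) -> None:
    n = len(template)
    for e, g in gains.items():
        if e in signals and g > 0:
            seg = signals[e][start_idx : start_idx + n]
            seg += g * template[: len(seg)]


def generate_recording(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one recording plus exact ground truth, bit-deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))

    signals: dict[str, np.ndarray] = {}
    for e in SCALP_ELECTRODES:
        sig = config.pink_noise_scale * pink_noise(n, rng)
        if e in POSTERIOR_ELECTRODES:
            sig = sig + config.alpha_amplitude_uv * _alpha_rhythm(n, fs, rng)
        signals[e] = sig
    for e in EAR_ELECTRODES:
        signals[e] = 0.2 * config.pink_noise_scale * pink_noise(n, rng)

    # --- IED events -----------------------------------------------------
    midpoints = _place_events(config, rng)
    events: list[EventLabel] = []
    annotations: list[Annotation] = []
    blocked: list[tuple[float, float]] = []  # intervals artifacts must avoid
    for mid in midpoints:
        start = mid - EVENT_DUR_S / 2
        end = mid + EVENT_DUR_S / 2
        if config.ied_field is not None:
            gains = dict(config.ied_field)
        else:
            center = rng.choice(FOCUS_ELECTRODES)
            gains = focal_field(str(center), config.field_decay)
        template = spike_wave_template(fs, rng)
        amp = config.ied_amplitude_uv * rng.uniform(0.7, 1.3)
        _inject(signals, amp * template, gains, int(round(start * fs)))

        events.append(EventLabel(start, end))
        blocked.append((start - 1.0, end + 1.0))
        for e, g in gains.items():
            if e in SCALP_ELECTRODES and g >= 0.5:
                annotations.append(Annotation("earlobe", e, "IED", start, end))
        for a, b in BIPOLAR_PAIRS:
            if abs(gains.get(a, 0.0) - gains.get(b, 0.0)) >= 0.3:
                annotations.append(Annotation("bipolar", f"{a}-{b}", "IED", start, end))

    # --- artifacts ------------------------------------------------------
    def clear_of_events(s: float, e: float) -> bool:
        return all(e <= lo or s >= hi for lo, hi in blocked)

    artifact_targets = {
        "EMG": TEMPORAL_ELECTRODES,
        "ECG": TEMPORAL_ELECTRODES,
        "movement": SCALP_ELECTRODES,
    }
    for kind, rate in config.artifact_rates.items():
        n_art = rng.poisson(rate * config.duration_s / 60.0)
        for _ in range(n_art):
            if kind == "EMG":
                dur = rng.uniform(0.5, 2.0)
                amp = rng.uniform(40, 80)
            elif kind == "ECG":
                dur = rng.uniform(4.0, 8.0)
                amp = rng.uniform(20, 35)
            else:
                dur = rng.uniform(1.0, 3.0)
                amp = rng.uniform(150, 300)
            start = rng.uniform(1.0, config.duration_s - dur - 1.0)
            if not clear_of_events(start, start + dur):
                continue
            n_samp = int(dur * fs)
            if kind == "EMG":
                wave = _emg_burst(n_samp, fs, rng)
            elif kind == "ECG":
                wave = _ecg_train(n_samp, fs, rng)
            else:
                wave = _movement_excursion(n_samp, fs, rng)
            target = str(rng.choice(artifact_targets[kind]))
            gains = focal_field(target, 0.5)
            _inject(signals, amp * wave, gains, int(round(start * fs)))
            annotations.append(Annotation("earlobe", target, "artifact", start, start + dur))
            for a, b in BIPOLAR_PAIRS:
                if target in (a, b):
                    annotations.append(
                        Annotation("bipolar", f"{a}-{b}", "artifact", start, start + dur)
                    )

    # --- background annotations at clean locations ----------------------
    n_bkg = max(int(config.duration_s / 60.0 * 2), 4)
    tries = 0
    placed = 0
    while placed < n_bkg and tries < 50 * n_bkg:
        tries += 1
        start = rng.uniform(1.0, config.duration_s - 3.0)
        if not clear_of_events(start, start + 2.0):
            continue
        e = str(rng.choice(SCALP_ELECTRODES))
        annotations.append(Annotation("earlobe", e, "background", start, start + 2.0))
        pairs = [p for p in BIPOLAR_PAIRS if e in p]
        a, b = pairs[int(rng.integers(len(pairs)))]
        annotations.append(Annotation("bipolar", f"{a}-{b}", "background", start, start + 2.0))
        placed += 1

    order = list(SCALP_ELECTRODES) + list(EAR_ELECTRODES)
    recording = Recording(
        signals=np.array([signals[e] for e in order]),
        electrode_labels=order,
        sampling_rate=fs,
        recording_id=f"sim-{config.seed}",
    )
    return recording, GroundTruth(events=merge_events(events), annotations=annotations)


# ---------------------------------------------------------------------------
# Direct segment-dataset generation
# ---------------------------------------------------------------------------

#: Direct segments are cut from the middle of a longer simulated stretch so
#: the preprocessing filter chain can be applied without edge effects.
_CONTEXT_SAMPLES = 3 * SEGMENT_SAMPLES


def _background_context(config: SimConfig, rng: np.random.Generator, bipolar: bool) -> np.ndarray:
    """3 s of background as one montage channel would present it.

    A bipolar derivation subtracts two electrodes, so its background is the
    difference of two independent noise processes; referential channels keep
    a single process plus (sometimes) the posterior alpha rhythm.
    """
    fs = config.sampling_rate
    n = _CONTEXT_SAMPLES
    sig = config.pink_noise_scale * pink_noise(n, rng)
    if bipolar:
        sig = sig - config.pink_noise_scale * pink_noise(n, rng)
    if rng.random() < 0.5:  # posterior-channel flavor
        t = np.arange(n) / fs
        sig = sig + config.alpha_amplitude_uv * rng.uniform(0.3, 1.0) * np.sin(
            2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi)
        )
    return sig


def _finish_segment(context: np.ndarray, config: SimConfig) -> np.ndarray:
    """Apply the standard filter cascade, then crop the central 1 s."""
    from iedscan.preprocess import FilterSpec, _design
    from scipy.signal import sosfiltfilt

    out = context
    for sos in _design(FilterSpec(), config.sampling_rate):
        out = sosfiltfilt(sos, out)
    return out[SEGMENT_SAMPLES : 2 * SEGMENT_SAMPLES].copy()


def generate_segment_dataset(config: SimConfig, n_per_class: int) -> list[Segment]:
    """Labeled 1 s segments mimicking what preprocessed montage channels present.

    Each segment is synthesized inside 3 s of context, passed through the
    standard filter cascade and cropped, so its spectral texture matches
    windows the detector sees at scan time.  IED segments place the
    spike-wave template near the window center with timing jitter (±0.2 s),
    amplitude spread (field gain x morphology jitter) and random polarity —
    bipolar derivations flip polarity depending on chain direction.
    Artifact segments draw one of the three morphologies.  Deterministic in
    the config seed; exactly ``n_per_class`` segments per class.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    segments: list[Segment] = []
    montages = ("earlobe", "bipolar")
    mid0 = SEGMENT_SAMPLES  # central 1 s of the context starts here

    for i in range(n_per_class):  # IED
        bipolar = i % 2 == 1
        ctx = _background_context(config, rng, bipolar)
        template = spike_wave_template(fs, rng)
        amp = config.ied_amplitude_uv * rng.uniform(0.7, 1.3)
        amp *= rng.uniform(0.3, 0.6) if bipolar else rng.uniform(0.5, 1.0)
        if rng.random() < 0.5:
            amp = -amp
        center = 0.5 + rng.uniform(-0.2, 0.2)
        i0 = mid0 + int((center - EVENT_DUR_S / 2) * fs)
        ctx[i0 : i0 + len(template)] += amp * template
        segments.append(
            Segment(_finish_segment(ctx, config), "IED",
                    ("synthetic", montages[i % 2], "sim", float(i)))
        )

    for i in range(n_per_class):  # artifact
        bipolar = i % 2 == 1
        ctx = _background_context(config, rng, bipolar)
        kind = ("EMG", "ECG", "movement")[int(rng.integers(3))]
        if kind == "EMG":
            dur = rng.uniform(0.3, 1.0)
            amp = rng.uniform(40, 80)
            wave = _emg_burst(int(dur * fs), fs, rng)
        elif kind == "ECG":
            dur = 1.0
            amp = rng.uniform(20, 35)
            wave = _ecg_train(SEGMENT_SAMPLES, fs, rng)
        else:
            dur = rng.uniform(0.6, 1.0)
            amp = rng.uniform(150, 300)
            wave = _movement_excursion(int(dur * fs), fs, rng)
        i0 = mid0 + int(rng.integers(0, max(SEGMENT_SAMPLES - len(wave), 1)))
        ctx[i0 : i0 + len(wave)] += amp * wave
        segments.append(
            Segment(_finish_segment(ctx, config), "artifact",
                    ("synthetic", montages[i % 2], "sim", float(i)))
        )

    for i in range(n_per_class):  # background
        ctx = _background_context(config, rng, i % 2 == 1)
        segments.append(
            Segment(_finish_segment(ctx, config), "background",
                    ("synthetic", montages[i % 2], "sim", float(i)))
        )
    return segments


# ---------------------------------------------------------------------------
# Oracle probabilities from ground truth
# ---------------------------------------------------------------------------

def oracle_frame_series(
    ground_truth: GroundTruth, duration: float, recording_id: str = "oracle"
) -> FrameSeries:
    """Probability frames an ideal classifier would emit given the ground truth.

    For each IED annotation, probability 1 is placed on the annotated channel
    in the sliding-window frame whose window is best centered on the
    annotation (all other values 0).  Running these frames through the
    decision stage must recover every ground-truth event and nothing else —
    the consistency check that generated ground truth satisfies the
    two-montage decision rule.
    """
    from iedscan.inference import _window_starts

    starts = _window_starts(duration)
    n_frames = len(starts)
    probs = np.zeros((n_frames, 2, N_FRAME_CHANNELS))
    ref_names = list(SCALP_ELECTRODES)
    bip_names = [f"{a}-{b}" for a, b in BIPOLAR_PAIRS]
    for ann in ground_truth.annotations:
        if ann.label != "IED":
            continue
        mid = 0.5 * (ann.start + ann.end)
        idx = int(np.clip(np.round((mid - 0.5) / 0.5), 0, n_frames - 1))
        if ann.montage_kind == "earlobe":
            probs[idx, 0, ref_names.index(ann.channel)] = 1.0
        else:
            probs[idx, 1, bip_names.index(ann.channel)] = 1.0
    return FrameSeries(
        instants=starts,
        probs=probs,
        duration=duration,
        ref_kind="earlobe",
        ref_channel_names=ref_names,
        ref_electrodes=[frozenset({e}) for e in ref_names],
        bipolar_channel_names=bip_names,
        bipolar_electrodes=[frozenset(p) for p in BIPOLAR_PAIRS],
        recording_id=recording_id,
    )
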