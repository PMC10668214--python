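"""Stage-2 decision mechanisms and event formation."""

import numpy as np
import pytest

from iedscan.decision import decide_instant, decide_series, detect_events, form_events
from iedscan.inference import FrameSeries, ProbabilityFrame
from iedscan.io import SCALP_ELECTRODES
from iedscan.montage import BIPOLAR_PAIRS

REF_NAMES = list(SCALP_ELECTRODES)
REF_SETS = [frozenset({e}) for e in REF_NAMES]
BIP_NAMES = [f"{a}-{b}" for a, b in BIPOLAR_PAIRS]
BIP_SETS = [frozenset(p) for p in BIPOLAR_PAIRS]


def make_frame(instant=0.0, ear=None, bip=None) -> ProbabilityFrame:
    probs = np.zeros((2, 19))
    for name, p in (ear or {}).items():
        probs[0, REF_NAMES.index(name)] = p
    for name, p in (bip or {}).items():
        probs[1, BIP_NAMES.index(name)] = p
    return ProbabilityFrame(instant, probs, "earlobe", REF_NAMES, REF_SETS, BIP_NAMES, BIP_SETS)


def make_series(frames: list[ProbabilityFrame]) -> FrameSeries:
    probs = np.stack([f.probs for f in frames])
    instants = np.array([f.instant for f in frames])
    return FrameSeries(
        instants=instants,
        probs=probs,
        duration=float(instants[-1] + 1.0) if len(frames) else 0.0,
        ref_kind="earlobe",
        ref_channel_names=REF_NAMES,
        ref_electrodes=REF_SETS,
        bipolar_channel_names=BIP_NAMES,
        bipolar_electrodes=BIP_SETS,
    )


def brute_force_decide(frame, threshold, mode, spatial_rule="overlap"):
    """Independent re-implementation with explicit loops over channels/pairs."""
    active_ear = []
    for i in range(19):
        if frame.probs[0, i] >= threshold:
            active_ear.append(i)
    active_bip = []
    for j in range(len(BIP_NAMES)):
        if frame.probs[1, j] >= threshold:
            active_bip.append(j)

    if mode == "SMDM":
        mx = max(frame.probs[0, i] for i in range(19))
        return mx >= threshold
    if len(active_ear) < 1:
        return False
    if len(active_bip) < 2:
        return False
    if spatial_rule == "overlap":
        for i in active_ear:
            for j in active_bip:
                for e in REF_SETS[i]:
                    if e in BIP_SETS[j]:
                        return True
        return False
    for i in active_ear:
        count = 0
        for j in active_bip:
            for e in REF_SETS[i]:
                if e in BIP_SETS[j]:
                    count += 1
                    break
        if count >= 2:
            return True
    return False


class TestDecideInstant:
    def test_all_zero_frame_negative_in_every_mode(self):
        frame = make_frame()
        for mode in ("TMDM", "SMDM", "common_average"):
            assert not decide_instant(frame, 0.5, mode).positive

    def test_tmdm_positive_with_shared_electrode(self):
        frame = make_frame(ear={"F3": 0.9}, bip={"F3-C3": 0.9, "C3-P3": 0.85})
        dec = decide_instant(frame, 0.5, "TMDM")
        assert dec.positive
        assert dec.active_ref == {REF_NAMES.index("F3")}
        assert dec.active_bipolar == {BIP_NAMES.index("F3-C3"), BIP_NAMES.index("C3-P3")}

    def test_tmdm_negative_when_spatially_uncorrelated(self):
        frame = make_frame(ear={"F3": 0.9}, bip={"T6-O2": 0.9, "P4-O2": 0.85})
        assert not decide_instant(frame, 0.5, "TMDM").positive
        assert decide_instant(frame, 0.5, "SMDM").positive

    def test_tmdm_needs_two_bipolar_activations(self):
        frame = make_frame(ear={"F3": 0.9}, bip={"F3-C3": 0.9})
        assert not decide_instant(frame, 0.5, "TMDM").positive

    def test_threshold_is_inclusive(self):
        frame = make_frame(ear={"F3": 0.5}, bip={"F3-C3": 0.5, "C3-P3": 0.5})
        assert decide_instant(frame, 0.5, "TMDM").positive

    def test_strict_spatial_rule_requires_two_supporting_pairs(self):
        one_pair = make_frame(ear={"F3": 0.9}, bip={"F3-C3": 0.9, "T6-O2": 0.9})
        assert decide_instant(one_pair, 0.5, "TMDM", "overlap").positive
        assert not decide_instant(one_pair, 0.5, "TMDM", "strict").positive
        two_pairs = make_frame(ear={"C3": 0.9}, bip={"F3-C3": 0.9, "C3-P3": 0.9})
        assert decide_instant(two_pairs, 0.5, "TMDM", "strict").positive

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            decide_instant(make_frame(), 1.1, "TMDM")

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            decide_instant(make_frame(), 0.5, "TMDM2")

    def test_zero_bipolar_rows_never_positive_under_tmdm(self, rng):
        for _ in range(50):
            probs = np.zeros((2, 19))
            probs[0] = rng.random(19)
            frame = ProbabilityFrame(0.0, probs, "earlobe", REF_NAMES, REF_SETS, BIP_NAMES, BIP_SETS)
            assert not decide_instant(frame, 0.3, "TMDM").positive


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["TMDM", "SMDM"])
    @pytest.mark.parametrize("spatial_rule", ["overlap", "strict"])
    def test_matches_brute_force_on_random_frames(self, mode, spatial_rule, rng):
        for _ in range(1000):
            probs = np.where(rng.random((2, 19)) < 0.7, 0.0, rng.random((2, 19)))
            probs[1, 18] = 0.0
            frame = ProbabilityFrame(
                0.0, probs, "earlobe", REF_NAMES, REF_SETS, BIP_NAMES, BIP_SETS
            )
            thr = float(rng.random())
            got = decide_instant(frame, thr, mode, spatial_rule).positive
            assert got == brute_force_decide(frame, thr, mode, spatial_rule)


class TestFormEvents:
    def test_adjacent_positives_union_their_windows(self):
        frames = [make_frame(instant=t) for t in (0.0, 0.5, 1.0, 1.5)]
        frames[2] = make_frame(instant=1.0, ear={"F3": 0.9}, bip={"F3-C3": 0.9, "C3-P3": 0.9})
        frames[3] = make_frame(instant=1.5, ear={"F3": 0.9}, bip={"F3-C3": 0.9, "C3-P3": 0.9})
        series = make_series(frames)
        events = form_events(decide_series(series, 0.5), series)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (1.0, 2.5)
        assert "F3" in events[0].channels and "F3-C3" in events[0].channels

    def test_distant_runs_stay_separate(self):
        active = dict(ear={"F3": 0.9}, bip={"F3-C3": 0.9, "C3-P3": 0.9})
        frames = [
            make_frame(instant=0.0, **active),
            make_frame(instant=0.5),
            make_frame(instant=1.0),
            make_frame(instant=1.5),
            make_frame(instant=2.0),
            make_frame(instant=2.5),
            make_frame(instant=3.0, **active),
        ]
        series = make_series(frames)
        events = form_events(decide_series(series, 0.5), series)
        assert [(e.start, e.end) for e in events] == [(0.0, 1.0), (3.0, 4.0)]

    def test_sub_second_gap_merges(self):
        active = dict(ear={"F3": 0.9}, bip={"F3-C3": 0.9, "C3-P3": 0.9})
        frames = [
            make_frame(instant=0.0, **active),
            make_frame(instant=0.5),
            make_frame(instant=1.0),
            make_frame(instant=1.5, **active),
        ]
        series = make_series(frames)
        events = form_events(decide_series(series, 0.5), series)
        assert [(e.start, e.end) for e in events] == [(0.0, 2.5)]

    def test_empty_input_empty_output(self):
        series = make_series([make_frame(instant=0.0)])
        assert form_events(decide_series(series, 0.5), series) == []

    def test_peak_probability_aggregated(self):
        frames = [
            make_frame(instant=0.0, ear={"F3": 0.7}, bip={"F3-C3": 0.8, "C3-P3": 0.6}),
            make_frame(instant=0.5, ear={"F3": 0.95}, bip={"F3-C3": 0.7, "C3-P3": 0.65}),
        ]
        series = make_series(frames)
        events = form_events(decide_series(series, 0.6), series)
        assert len(events) == 1
        assert events[0].peak_probability == pytest.approx(0.95)

    def test_merging_idempotent(self, rng):
        frames = []
        for t in range(40):
            if rng.random() < 0.4:
                frames.append(
                    make_frame(instant=t * 0.5, ear={"F3": 0.9}, bip={"F3-C3": 0.9, "C3-P3": 0.9})
                )
            else:
                frames.append(make_frame(instant=t * 0.5))
        series = make_series(frames)
        events = form_events(decide_series(series, 0.5), series)
        for a, b in zip(events, events[1:]):
            assert b.start - a.end >= 1.0


class TestThresholdMonotonicity:
    def test_positive_instants_nested_across_thresholds(self, rng):
        """Raising the threshold can only remove positive instants."""
        frames = []
        for t in range(120):
            probs = np.where(rng.random((2, 19)) < 0.8, 0.0, rng.random((2, 19)))
            probs[1, 18] = 0.0
            frames.append(
                ProbabilityFrame(t * 0.5, probs, "earlobe", REF_NAMES, REF_SETS, BIP_NAMES, BIP_SETS)
            )
        series = make_series(frames)
        prev_positives = None
        for thr in np.linspace(0.0, 1.0, 21):
            decisions = decide_series(series, float(thr))
            positives = {d.instant for d in decisions if d.positive}
            if prev_positives is not None:
                assert positives.issubset(prev_positives)
            prev_positives = positives

    def test_event_count_non_increasing_on_unimodal_profiles(self, rng):
        """With one temporal probability bump per event (the structure real
        detections have), detected-event count never rises with threshold."""
        series = make_series(unimodal_series_frames(rng))
        thresholds = np.linspace(0.0, 1.0, 21)
        counts = [len(detect_events(series, float(t))) for t in thresholds]
        # threshold 0 is degenerate under the inclusive (>=) comparison: every
        # instant is positive and all windows merge into one event
        assert counts[0] == 1
        assert all(a >= b for a, b in zip(counts[1:], counts[2:]))
        assert counts[1] > 0 and counts[-1] == 0


def unimodal_series_frames(rng, n_events: int = 12, duration_s: float = 120.0):
    """Frames whose IED probabilities form one Gaussian bump per event."""
    instants = np.arange(int((duration_s - 1.0) / 0.5) + 1) * 0.5
    mids = np.linspace(4.0, duration_s - 4.0, n_events)
    frames = []
    bumps = [(m, float(rng.uniform(0.3, 1.0))) for m in mids]
    for t in instants:
        ear, bip = {}, {}
        for mid, peak in bumps:
            p = peak * np.exp(-(((t + 0.5) - mid) / 0.4) ** 2)
            if p > 1e-3:
                ear["F3"] = max(ear.get("F3", 0.0), p)
                bip["F3-C3"] = max(bip.get("F3-C3", 0.0), p)
                bip["C3-P3"] = max(bip.get("C3-P3", 0.0), p)
        frames.append(make_frame(instant=float(t), ear=ear, bip=bip))
    return frames
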