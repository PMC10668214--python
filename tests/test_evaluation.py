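"""Event matching, PR curves, operating points, kappa and bootstrap CIs."""

import numpy as np
import pytest

from iedscan.evaluation import (
    EvaluationError,
    Kappa,
    PrCurve,
    PrPoint,
    bootstrap_ci,
    cohen_kappa_epochs,
    events_to_epoch_array,
    fpr_at_sensitivity,
    match_events,
    pr_curve,
)
from iedscan.io import EventLabel, ValidationError


def ev(start, end):
    return EventLabel(start, end)


class TestMatchEvents:
    def test_full_overlap_is_tp(self):
        m = match_events([ev(0, 2)], [ev(1, 2)])
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_disjoint_is_fp_and_fn(self):
        m = match_events([ev(0, 1)], [ev(2, 3)])
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_small_overlap_ratio_rejected(self):
        m = match_events([ev(0, 4)], [ev(3.9, 5.9)])  # overlap 0.1, min dur 2.0
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_one_to_one_matching(self):
        # one long detection spans two labels; only one label can match
        m = match_events([ev(0, 3)], [ev(0.2, 0.8), ev(2.0, 2.8)])
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)

    def test_greedy_prefers_larger_overlap(self):
        m = match_events([ev(0, 1), ev(1.5, 3)], [ev(0.8, 2.9)])
        assert m.tp == 1 and m.fp == 1
        det, _ = m.matched_pairs[0]
        assert det.start == 1.5  # overlap 1.4 beats overlap 0.2

    def test_swap_symmetry(self, rng):
        dets = [ev(t, t + rng.uniform(0.3, 1.0)) for t in np.arange(0, 40, 2.5)]
        labs = [ev(t + rng.uniform(0, 1.2), t + 1.8) for t in np.arange(0.2, 38, 3.1)]
        fwd = match_events(dets, labs)
        rev = match_events(labs, dets)
        assert fwd.tp == rev.tp and fwd.fp == rev.fn and fwd.fn == rev.fp

    def test_overlapping_detections_rejected(self):
        with pytest.raises(ValidationError):
            match_events([ev(0, 2), ev(1, 3)], [ev(0, 1)])

    def test_counts_partition_inputs(self, rng):
        dets = [ev(t, t + 1) for t in np.arange(0, 50, 2.0)]
        labs = [ev(t + 0.4, t + 1.2) for t in np.arange(0, 30, 4.0)]
        m = match_events(dets, labs)
        assert m.tp + m.fp == len(dets)
        assert m.tp + m.fn == len(labs)


class TestOperatingPoint:
    def test_hand_computed_fixture(self):
        # at tau=0.6: TP=8, FN=2, FP=3 over 60 minutes
        points = [
            PrPoint(0.4, 1.0, 0.5, 10 / 60.0),
            PrPoint(0.6, 8 / 10, 8 / 11, 3 / 60.0),
            PrPoint(0.8, 0.5, 1.0, 0.0),
        ]
        curve = PrCurve(points=points, auprc=0.9)
        op = fpr_at_sensitivity(curve, target=0.8)
        assert op.threshold == 0.6
        assert op.fp_per_min == pytest.approx(0.05, abs=1e-12)
        expected_f1 = 2 * (8 / 11) * 0.8 / ((8 / 11) + 0.8)
        assert op.f1 == pytest.approx(expected_f1, abs=1e-9)
        assert op.f1 == pytest.approx(0.7619, abs=1e-4)

    def test_perfect_detector_takes_highest_threshold(self):
        points = [PrPoint(t, 1.0, 1.0, 0.0) for t in (0.2, 0.5, 0.9)]
        op = fpr_at_sensitivity(PrCurve(points, 1.0), target=0.8)
        assert op.threshold == 0.9 and op.fp_per_min == 0.0 and op.f1 == 1.0

    def test_never_firing_detector_flagged(self):
        points = [PrPoint(t, 0.0, 1.0, 0.0) for t in (0.2, 0.5)]
        op = fpr_at_sensitivity(PrCurve(points, 0.0), target=0.8)
        assert not op.target_reached
        assert op.threshold == 0.2


class TestKappa:
    def test_identical_event_lists(self):
        events = [ev(1, 2), ev(5, 6.5)]
        assert cohen_kappa_epochs(events, list(events), 10.0) == 1.0

    def test_hand_computed_contingency(self):
        # arrays a = 1111000000, b = 1100000000 over 10 epochs
        a = [ev(0, 4)]
        b = [ev(0, 2)]
        k = cohen_kappa_epochs(a, b, 10.0)
        assert float(k) == pytest.approx(0.24 / 0.44, abs=1e-9)

    def test_degenerate_disagreement(self):
        k = cohen_kappa_epochs([ev(0, 10)], [], 10.0)
        assert float(k) == 0.0
        assert k.degenerate

    def test_identical_constant_arrays(self):
        k = cohen_kappa_epochs([], [], 10.0)
        assert float(k) == 1.0 and k.degenerate

    def test_epoch_array_construction(self):
        arr = events_to_epoch_array([ev(1.2, 1.4), ev(3.9, 4.1)], 6.0)
        assert arr.tolist() == [0, 1, 0, 1, 1, 0]

    def test_range_and_self_agreement_on_random_pairs(self, rng):
        for _ in range(2000):
            n = int(rng.integers(4, 30))
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            events_a = [ev(i, i + 1) for i in range(n) if a[i]]
            events_b = [ev(i, i + 1) for i in range(n) if b[i]]
            k = cohen_kappa_epochs(events_a, events_b, float(n))
            assert -1.0 - 1e-9 <= float(k) <= 1.0 + 1e-9
            if events_a and len(events_a) < n:
                assert cohen_kappa_epochs(events_a, list(events_a), float(n)) == 1.0

    def test_matches_sklearn_on_non_degenerate_pairs(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(200):
            n = int(rng.integers(6, 40))
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            if a.min() == a.max() or b.min() == b.max() or np.array_equal(a, b):
                continue
            events_a = [ev(i, i + 1) for i in range(n) if a[i]]
            events_b = [ev(i, i + 1) for i in range(n) if b[i]]
            got = cohen_kappa_epochs(events_a, events_b, float(n))
            assert float(got) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa_epochs([], [], 0.5)


class _StaticSeries:
    """Minimal FrameSeries stand-in for pooling tests (duration only)."""

    def __init__(self, duration, recording_id="r"):
        self.duration = duration
        self.recording_id = recording_id


class TestPrCurvePooling:
    def _series_and_labels(self):
        from tests.test_decision import make_frame, make_series

        active = dict(ear={"F3": 1.0}, bip={"F3-C3": 1.0, "C3-P3": 1.0})
        # recording 1: one event, perfectly detected
        frames1 = [make_frame(instant=t * 0.5) for t in range(20)]
        frames1[4] = make_frame(instant=2.0, **active)
        labels1 = [ev(2.2, 2.6)]
        # recording 2: one event missed, one false alarm
        frames2 = [make_frame(instant=t * 0.5) for t in range(20)]
        frames2[10] = make_frame(instant=5.0, **active)
        labels2 = [ev(8.2, 8.6)]
        return (
            [make_series(frames1), make_series(frames2)],
            [labels1, labels2],
        )

    def test_mixed_recordings_pool_correctly(self):
        series, labels = self._series_and_labels()
        curve = pr_curve(series, labels, thresholds=[0.5])
        point = curve.points[0]
        # pooled: TP=1, FP=1, FN=1 -> sens 0.5, prec 0.5
        assert (point.tp, point.fp, point.fn) == (1, 1, 1)
        assert point.sensitivity == pytest.approx(0.5)
        assert point.precision == pytest.approx(0.5)

    def test_pooled_counts_not_averaged_per_recording(self):
        from tests.test_decision import make_frame, make_series

        active = dict(ear={"F3": 1.0}, bip={"F3-C3": 1.0, "C3-P3": 1.0})
        # recording 1: nine events, all detected (sens 1.0)
        frames1 = [make_frame(instant=t * 0.5) for t in range(80)]
        labels1 = []
        for i in range(9):
            idx = 4 + 8 * i
            frames1[idx] = make_frame(instant=idx * 0.5, **active)
            labels1.append(ev(idx * 0.5 + 0.2, idx * 0.5 + 0.6))
        # recording 2: one event, missed (sens 0.0)
        frames2 = [make_frame(instant=t * 0.5) for t in range(80)]
        labels2 = [ev(8.2, 8.6)]
        curve = pr_curve(
            [make_series(frames1), make_series(frames2)], [labels1, labels2],
            thresholds=[0.5],
        )
        pooled = curve.points[0].sensitivity
        assert pooled == pytest.approx(0.9)  # 9 TP / 10 labels, not (1.0 + 0.0)/2
        assert pooled != pytest.approx(0.5)

    def test_perfect_detector_auprc_one(self):
        from tests.test_decision import make_frame, make_series

        active = dict(ear={"F3": 1.0}, bip={"F3-C3": 1.0, "C3-P3": 1.0})
        frames = [make_frame(instant=t * 0.5) for t in range(30)]
        frames[6] = make_frame(instant=3.0, **active)
        series = make_series(frames)
        labels = [ev(3.2, 3.6)]
        curve = pr_curve([series], [labels], thresholds=np.arange(0.1, 1.0, 0.1))
        assert curve.auprc == pytest.approx(1.0)
        for p in curve.points:
            assert p.sensitivity == 1.0 and p.precision == 1.0

    def test_null_detector_auprc_zero(self):
        from tests.test_decision import make_frame, make_series

        frames = [make_frame(instant=t * 0.5) for t in range(30)]
        series = make_series(frames)
        curve = pr_curve([series], [[ev(3.2, 3.6)]], thresholds=[0.25, 0.5, 0.75])
        assert curve.auprc == pytest.approx(0.0)
        assert all(p.sensitivity == 0.0 for p in curve.points)

    def test_no_labels_anywhere_rejected(self):
        from tests.test_decision import make_frame, make_series

        series = make_series([make_frame(instant=0.0)])
        with pytest.raises(EvaluationError):
            pr_curve([series], [[]], thresholds=[0.5])

    def test_thresholds_must_increase(self):
        from tests.test_decision import make_frame, make_series

        series = make_series([make_frame(instant=0.0)])
        with pytest.raises(ValueError):
            pr_curve([series], [[ev(0.1, 0.3)]], thresholds=[0.5, 0.5])


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        lo, hi = bootstrap_ci(lambda recs: 0.7, list(range(5)), iterations=200, seed=0)
        assert lo == hi == 0.7

    def test_deterministic_under_seed(self):
        vals = {0: 0.2, 1: 0.9, 2: 0.5}

        def metric(recs):
            return float(np.mean([vals[r] for r in recs]))

        a = bootstrap_ci(metric, [0, 1, 2], iterations=300, seed=42)
        b = bootstrap_ci(metric, [0, 1, 2], iterations=300, seed=42)
        assert a == b

    def test_two_recording_extremes(self):
        def metric(recs):
            return float(np.mean(recs))

        lo, hi = bootstrap_ci(metric, [0.0, 1.0], iterations=1000, seed=1)
        # each replicate draws from {0, 0.5, 1}; with 1000 draws both extremes appear
        assert lo == 0.0 and hi == 1.0

    def test_undefined_replicates_redrawn(self):
        calls = {"n": 0}

        def metric(recs):
            calls["n"] += 1
            if all(r == 0 for r in recs):
                raise EvaluationError("no labels drawn")
            return float(np.mean(recs))

        lo, hi = bootstrap_ci(metric, [0, 1], iterations=200, seed=3)
        assert calls["n"] >= 200
        assert 0.0 <= lo <= hi <= 1.0

    def test_needs_two_recordings(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda r: 0.0, [1], iterations=10, seed=0)
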