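"""Event-level and epoch-level scoring of IED detection systems.

A detection counts as a true positive when its overlap with an expert event
label reaches at least half of the shorter of the two intervals; matching is
greedy one-to-one in decreasing overlap order.  Precision-recall curves pool
true/false positives and false negatives across recordings (micro-averaged),
false-positive rates are expressed per minute of EEG, and chance-corrected
agreement uses Cohen's kappa over 1 s epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from iedscan.decision import Detection, detect_events
from iedscan.inference import FrameSeries
from iedscan.io import EventLabel, ValidationError


class EvaluationError(ValueError):
    """The evaluation is undefined on this input (e.g., no labels at all)."""


# ---------------------------------------------------------------------------
# Overlap matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple]


def _check_sorted_disjoint(intervals: Sequence, what: str) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"{what} overlap: [{a.start}, {a.end}) and [{b.start}, {b.end}); "
                "apply the merging rule first"
            )


def _overlap(a, b) -> float:
    return max(0.0, min(a.end, b.end) - max(a.start, b.start))


def match_events(
    detections: Sequence,
    labels: Sequence[EventLabel],
    min_overlap_fraction: float = 0.5,
    denominator: str = "min",
) -> MatchResult:
    """Greedy one-to-one matching of detections to expert event labels.

    A pair is eligible when overlap / denominator >= ``min_overlap_fraction``,
    where the denominator is the shorter interval's duration (``"min"``,
    default), the label's (``"label"``) or the detection's (``"detection"``).
    Unmatched detections count as false positives, unmatched labels as false
    negatives.  Both input lists must be sorted and internally non-overlapping.
    """
    detections = sorted(detections, key=lambda d: (d.start, d.end))
    labels = sorted(labels, key=lambda l: (l.start, l.end))
    _check_sorted_disjoint(detections, "detections")
    _check_sorted_disjoint(labels, "labels")

    candidates = []
    for i, det in enumerate(detections):
        for j, lab in enumerate(labels):
            if lab.start >= det.end:
                break
            ov = _overlap(det, lab)
            if ov <= 0:
                continue
            if denominator == "min":
                denom = min(det.end - det.start, lab.end - lab.start)
            elif denominator == "label":
                denom = lab.end - lab.start
            elif denominator == "detection":
                denom = det.end - det.start
            else:
                raise ValueError(f"unknown denominator {denominator!r}")
            if ov / denom >= min_overlap_fraction:
                candidates.append((ov, i, j))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_det: set[int] = set()
    used_lab: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_det or j in used_lab:
            continue
        used_det.add(i)
        used_lab.add(j)
        pairs.append((detections[i], labels[j]))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(detections) - tp,
        fn=len(labels) - tp,
        matched_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Precision-recall over thresholds
# ---------------------------------------------------------------------------

@dataclass
class PrPoint:
    threshold: float
    sensitivity: float
    precision: float
    fp_per_min: float
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class PrCurve:
    points: list[PrPoint]
    auprc: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    precision: float
    fp_per_min: float
    f1: float
    target_reached: bool


def _auprc_from_points(sens: np.ndarray, prec: np.ndarray) -> float:
    """Trapezoidal area under precision over sensitivity.

    Several thresholds can land on the same sensitivity; only the best
    precision among them lies on the operating frontier, so ties are
    collapsed to their maximum before integrating.  The curve is extended to
    sensitivity 0 at the highest-precision point.
    """
    uniq = np.unique(sens)
    best = np.array([prec[sens == u].max() for u in uniq])
    s = np.concatenate([[0.0], uniq])
    p = np.concatenate([[best.max()], best])
    return float(np.trapezoid(p, s))


def _counts_per_recording(
    series_list: Sequence[FrameSeries],
    labels_list: Sequence[Sequence[EventLabel]],
    thresholds: np.ndarray,
    mode: str,
    spatial_rule: str,
) -> np.ndarray:
    """(n_recordings, n_thresholds, 3) array of TP/FP/FN counts."""
    counts = np.zeros((len(series_list), len(thresholds), 3), dtype=np.int64)
    for r, (series, labels) in enumerate(zip(series_list, labels_list)):
        for t, thr in enumerate(thresholds):
            detections = detect_events(series, float(thr), mode, spatial_rule)
            m = match_events(detections, list(labels))
            counts[r, t] = (m.tp, m.fp, m.fn)
    return counts


def _curve_from_counts(
    counts: np.ndarray, thresholds: np.ndarray, total_minutes: float
) -> PrCurve:
    pooled = counts.sum(axis=0)  # (n_thresholds, 3)
    points = []
    for t, thr in enumerate(thresholds):
        tp, fp, fn = (int(v) for v in pooled[t])
        sens = tp / (tp + fn) if tp + fn > 0 else 0.0
        prec = tp / (tp + fp) if tp + fp > 0 else 1.0  # no detections: precision 1
        points.append(
            PrPoint(float(thr), sens, prec, fp / total_minutes, tp, fp, fn)
        )
    sens = np.array([p.sensitivity for p in points])
    prec = np.array([p.precision for p in points])
    return PrCurve(points=points, auprc=_auprc_from_points(sens, prec))


def pr_curve(
    series_list: Sequence[FrameSeries],
    labels_list: Sequence[Sequence[EventLabel]],
    mode: str = "TMDM",
    thresholds: Sequence[float] | None = None,
    spatial_rule: str = "overlap",
    bootstrap_iterations: int = 0,
    seed: int = 0,
) -> PrCurve:
    """Pooled PR curve of the detection system over a set of recordings.

    For each threshold the decision stage and event formation are re-run on
    every recording's frame series, counts are pooled, and sensitivity,
    precision and FP/min are computed from the sums.  With
    ``bootstrap_iterations > 0`` a percentile CI for the AUPRC is estimated
    by resampling whole recordings with replacement.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 1.0, 0.05), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0) or thresholds.min() <= 0 or thresholds.max() >= 1:
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    if sum(len(l) for l in labels_list) == 0:
        raise EvaluationError("no event labels in any recording; sensitivity undefined")
    if len(series_list) != len(labels_list):
        raise ValueError("series_list and labels_list must align")

    minutes = np.array([s.duration / 60.0 for s in series_list])
    counts = _counts_per_recording(series_list, labels_list, thresholds, mode, spatial_rule)
    curve = _curve_from_counts(counts, thresholds, float(minutes.sum()))

    if bootstrap_iterations > 0:
        def auprc_of(index: np.ndarray) -> float:
            sub = counts[index]
            if sub.sum(axis=(0, 1))[2] + sub.sum(axis=(0, 1))[0] == 0:
                raise EvaluationError("replicate without labels")
            return _curve_from_counts(sub, thresholds, float(minutes[index].sum())).auprc

        low, high = _bootstrap_indices_ci(
            auprc_of, len(series_list), bootstrap_iterations, seed
        )
        curve.ci_low, curve.ci_high = low, high
    return curve


def fpr_at_sensitivity(curve: PrCurve, target: float = 0.8) -> OperatingPoint:
    """Operating point at the largest threshold whose sensitivity reaches target.

    When no threshold reaches the target sensitivity, the lowest-threshold
    point is returned with ``target_reached=False``.
    """
    if not curve.points:
        raise ValueError("empty PR curve")
    eligible = [p for p in curve.points if p.sensitivity >= target]
    if eligible:
        point = max(eligible, key=lambda p: p.threshold)
        reached = True
    else:
        point = min(curve.points, key=lambda p: p.threshold)
        reached = False
    denom = point.precision + point.sensitivity
    f1 = 2 * point.precision * point.sensitivity / denom if denom > 0 else 0.0
    return OperatingPoint(
        threshold=point.threshold,
        sensitivity=point.sensitivity,
        precision=point.precision,
        fp_per_min=point.fp_per_min,
        f1=f1,
        target_reached=reached,
    )


def per_recording_table(
    series_list: Sequence[FrameSeries],
    labels_list: Sequence[Sequence[EventLabel]],
    threshold: float,
    mode: str = "TMDM",
    spatial_rule: str = "overlap",
) -> pd.DataFrame:
    """Recording-wise sensitivity, precision and FP/min at one threshold."""
    rows = []
    for series, labels in zip(series_list, labels_list):
        detections = detect_events(series, threshold, mode, spatial_rule)
        m = match_events(detections, list(labels))
        minutes = series.duration / 60.0
        rows.append(
            {
                "recording_id": series.recording_id,
                "n_labels": len(labels),
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "sensitivity": m.tp / (m.tp + m.fn) if m.tp + m.fn else np.nan,
                "precision": m.tp / (m.tp + m.fp) if m.tp + m.fp else np.nan,
                "fp_per_min": m.fp / minutes,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Epoch-wise Cohen's kappa
# ---------------------------------------------------------------------------

class Kappa(float):
    """A kappa value carrying a degeneracy flag for constant-array cases."""

    degenerate: bool = False

    def __new__(cls, value: float, degenerate: bool = False) -> "Kappa":
        obj = super().__new__(cls, value)
        obj.degenerate = degenerate
        return obj


def events_to_epoch_array(events: Sequence, duration: float) -> np.ndarray:
    """Binary per-1 s-epoch indicator: epoch i is 1 iff [i, i+1) overlaps an event."""
    n = int(np.floor(duration))
    arr = np.zeros(n, dtype=np.int64)
    for ev in events:
        first = max(int(np.floor(ev.start)), 0)
        last = min(int(np.ceil(ev.end)), n)
        arr[first:last] = 1
    return arr


def cohen_kappa_epochs(events_a: Sequence, events_b: Sequence, duration: float) -> Kappa:
    """Chance-corrected epoch-wise agreement between two event lists.

    Conventions for degenerate marginals: identical arrays (including
    constant ones) give kappa 1; when chance agreement p_e reaches 1 with
    non-identical arrays, or both observed and chance agreement vanish,
    kappa is 0 with the ``degenerate`` flag set.
    """
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    a = events_to_epoch_array(events_a, duration)
    b = events_to_epoch_array(events_b, duration)
    if np.array_equal(a, b):
        return Kappa(1.0, degenerate=bool(a.min() == a.max()))
    constant = a.min() == a.max() or b.min() == b.max()
    po = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    pe = float(pa * pb + (1 - pa) * (1 - pb))
    if abs(1.0 - pe) < 1e-15:
        return Kappa(0.0, degenerate=True)
    if constant:
        return Kappa((po - pe) / (1 - pe), degenerate=True)
    from sklearn.metrics import cohen_kappa_score

    return Kappa(float(cohen_kappa_score(a, b)), degenerate=False)


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals
# ---------------------------------------------------------------------------

def _bootstrap_indices_ci(
    metric_of_indices: Callable[[np.ndarray], float],
    n: int,
    iterations: int,
    seed: int,
    level: float = 0.95,
    max_redraws: int = 100_000,
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    values = []
    redraws = 0
    while len(values) < iterations:
        idx = rng.integers(0, n, size=n)
        try:
            v = metric_of_indices(idx)
        except EvaluationError:
            redraws += 1
            if redraws > max_redraws:
                raise EvaluationError(
                    "bootstrap could not draw enough valid replicates"
                ) from None
            continue
        if np.isnan(v):
            redraws += 1
            continue
        values.append(v)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_ci(
    metric_fn: Callable[[list], float],
    recordings: list,
    iterations: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a pooled metric, resampling recordings.

    ``metric_fn`` receives a list of recordings (any per-recording objects)
    and returns the pooled metric.  Recordings, not events, are the
    independent units.  Replicates on which the metric is undefined (raises
    :class:`EvaluationError` or returns NaN) are redrawn; deterministic under
    ``seed``.
    """
    if len(recordings) < 2:
        raise ValueError("bootstrap needs at least 2 recordings")

    def of_indices(idx: np.ndarray) -> float:
        return metric_fn([recordings[i] for i in idx])

    return _bootstrap_indices_ci(of_indices, len(recordings), iterations, seed, level)


def plot_pr_curve(curve: PrCurve, path) -> None:
    """Save a simple PR-curve figure (sensitivity vs precision)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sens = [p.sensitivity for p in curve.points]
    prec = [p.precision for p in curve.points]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(sens, prec, marker="o", lw=1)
    ax.set_xlabel("Sensitivity (recall)")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.set_title(f"AUPRC = {curve.auprc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
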