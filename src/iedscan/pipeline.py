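"""Glue joining the pipeline stages for the CLI and the examples.

Everything here is a thin composition of the module-level operations:
standardize → montage → segment/scan → decide → evaluate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from iedscan.decision import Detection, detect_events
from iedscan.evaluation import OperatingPoint, PrCurve, fpr_at_sensitivity, pr_curve
from iedscan.inference import FrameSeries, scan_recording
from iedscan.io import Annotation, EventLabel, Recording
from iedscan.models import ClassifierModel, TrainConfig, build_classifier, train_classifier
from iedscan.montage import derive_montage
from iedscan.preprocess import FilterSpec, standardize
from iedscan.segmentation import Segment, balance_classes, segment_annotation


def filter_spec_from_config(cfg: dict) -> FilterSpec:
    p = cfg["preprocess"]
    return FilterSpec(
        highpass_hz=p["highpass_hz"],
        lowpass_hz=p["lowpass_hz"],
        notch_hz=p["notch_hz"],
        order=p["order"],
        zero_phase=p["zero_phase"],
    )


def segments_from_recording(
    recording: Recording,
    annotations: list[Annotation],
    spec: FilterSpec = FilterSpec(),
    target_rate: float = 256.0,
) -> list[Segment]:
    """Preprocess a recording and cut all channel-wise annotations into segments."""
    rec = standardize(recording, spec, target_rate)
    views = {
        "earlobe": derive_montage(rec, "earlobe"),
        "bipolar": derive_montage(rec, "bipolar"),
    }
    segments: list[Segment] = []
    for ann in annotations:
        view = views[ann.montage_kind]
        segments.extend(
            segment_annotation(ann, view, rec.sampling_rate, rec.recording_id)
        )
    return segments


def train_from_segments(
    segments: list[Segment],
    architecture: str = "tcn",
    hyperparameters: dict | None = None,
    config: TrainConfig = TrainConfig(),
) -> ClassifierModel:
    """Balance classes, build and fit a classifier."""
    balanced = balance_classes(segments, seed=config.seed)
    model = build_classifier(architecture, hyperparameters)
    train_classifier(model, balanced, config)
    return model


def scan_preprocessed(
    recording: Recording,
    model: ClassifierModel,
    spec: FilterSpec = FilterSpec(),
    ref_montage: str = "earlobe",
    model_fingerprint: str | None = None,
) -> FrameSeries:
    """Standardize a raw recording and run the stage-1 sliding-window scan."""
    rec = standardize(recording, spec)
    return scan_recording(
        rec,
        model,
        ref_montage=ref_montage,
        expected_fingerprint=spec.fingerprint(),
        model_fingerprint=model_fingerprint,
    )


def detect_recording(
    recording: Recording,
    model: ClassifierModel,
    threshold: float,
    spec: FilterSpec = FilterSpec(),
    mode: str = "TMDM",
    spatial_rule: str = "overlap",
    ref_montage: str = "earlobe",
) -> list[Detection]:
    """Full two-stage detection on one raw recording."""
    series = scan_preprocessed(recording, model, spec, ref_montage)
    return detect_events(series, threshold, mode, spatial_rule)


def evaluate_system(
    series_list: list[FrameSeries],
    labels_list: list[list[EventLabel]],
    mode: str = "TMDM",
    thresholds=None,
    target_sensitivity: float = 0.8,
    spatial_rule: str = "overlap",
    bootstrap_iterations: int = 0,
    seed: int = 0,
) -> tuple[PrCurve, OperatingPoint]:
    """PR curve over recordings plus the fixed-sensitivity operating point."""
    curve = pr_curve(
        series_list,
        labels_list,
        mode=mode,
        thresholds=thresholds,
        spatial_rule=spatial_rule,
        bootstrap_iterations=bootstrap_iterations,
        seed=seed,
    )
    op = fpr_at_sensitivity(curve, target=target_sensitivity)
    return curve, op
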