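"""Training and cross-validation of the EEG segment classifiers.

Training minimizes softmax cross-entropy with Adam under a one-cycle
learning-rate schedule (warmup then cosine annealing), which converges
quickly and robustly at the small epoch budgets used here.  Cross-validation
is stratified five-fold on (label, montage), with class balancing applied to
the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc, confusion_matrix, precision_recall_curve

from iedscan.models._nn import Adam, cross_entropy, cross_entropy_grad, one_cycle_lr, softmax
from iedscan.models.base import CLASS_INDEX, CLASS_ORDER, ClassifierModel, build_classifier, standardize_segments
from iedscan.segmentation import DataError, Segment, balance_classes, stratified_folds


@dataclass
class TrainConfig:
    epochs: int = 20
    max_learning_rate: float = 1e-2
    batch_size: int = 64
    seed: int = 0
    scheduler: str = "one_cycle"


@dataclass
class TrainReport:
    epoch_losses: list[float]
    final_loss: float


@dataclass
class CvReport:
    """Per-fold confusion matrices (class order IED, artifact, background),
    overall true-positive rates, and one-vs-rest IED PR curves with AUPRC."""

    confusion_matrices: list[np.ndarray] = field(default_factory=list)
    overall_tpr: list[float] = field(default_factory=list)
    ied_pr_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    ied_auprc: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "mean_overall_tpr": float(np.mean(self.overall_tpr)),
            "sd_overall_tpr": float(np.std(self.overall_tpr)),
            "mean_ied_auprc": float(np.mean(self.ied_auprc)),
            "sd_ied_auprc": float(np.std(self.ied_auprc)),
        }


def _segments_to_arrays(segments: list[Segment]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([seg.samples for seg in segments])
    y = np.array([CLASS_INDEX[seg.label] for seg in segments], dtype=np.int64)
    return x, y


def train_classifier(
    model: ClassifierModel,
    segments: list[Segment],
    config: TrainConfig = TrainConfig(),
) -> TrainReport:
    """Fit the model in place on labeled segments; returns per-epoch losses.

    The seed in ``config`` fully determines weight initialization, dropout
    and mini-batch order, so identical runs produce identical weights.
    """
    labels = {seg.label for seg in segments}
    missing = set(CLASS_ORDER) - labels
    if missing:
        raise DataError(f"training set lacks class(es): {sorted(missing)}")

    model.initialize(config.seed)
    x_raw, y = _segments_to_arrays(segments)
    x = standardize_segments(x_raw)
    n = x.shape[0]
    order_rng = np.random.default_rng(config.seed + 1)

    opt = Adam(model.params, model.grads)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    step = 0
    epoch_losses: list[float] = []
    for _epoch in range(config.epochs):
        perm = order_rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = perm[i : i + config.batch_size]
            logits = model._forward(x[idx], train=True)
            probs = softmax(logits)
            losses.append(cross_entropy(probs, y[idx]))
            model._backward(cross_entropy_grad(probs, y[idx]))
            lr = (
                one_cycle_lr(step, total_steps, config.max_learning_rate)
                if config.scheduler == "one_cycle"
                else config.max_learning_rate
            )
            opt.step(lr)
            step += 1
        epoch_losses.append(float(np.mean(losses)))
    model.fitted = True
    return TrainReport(epoch_losses=epoch_losses, final_loss=epoch_losses[-1])


def evaluate_fold(model: ClassifierModel, segments: list[Segment]) -> dict:
    """Confusion matrix, overall TPR and IED one-vs-rest PR on a test fold."""
    x, y = _segments_to_arrays(segments)
    probs = model.predict_proba(x)
    pred = probs.argmax(axis=1)
    cm = confusion_matrix(y, pred, labels=range(len(CLASS_ORDER)))
    tpr = float(np.trace(cm) / cm.sum())
    ied_scores = probs[:, CLASS_INDEX["IED"]]
    ied_true = (y == CLASS_INDEX["IED"]).astype(int)
    precision, recall, _ = precision_recall_curve(ied_true, ied_scores)
    auprc = float(auc(recall, precision))
    return {
        "confusion_matrix": cm,
        "overall_tpr": tpr,
        "pr_curve": (recall, precision),
        "ied_auprc": auprc,
    }


def cross_validate(
    architecture_name: str,
    segments: list[Segment],
    k: int = 5,
    config: TrainConfig = TrainConfig(),
    hyperparameters: dict | None = None,
) -> CvReport:
    """Stratified k-fold cross-validation of one architecture.

    Training folds are class-balanced by oversampling before fitting; the
    held-out fold is evaluated as-is.
    """
    folds = stratified_folds(segments, k=k, seed=config.seed)
    report = CvReport()
    for fold in range(k):
        train_segs = [segments[i] for i in folds.train_indices(fold)]
        test_segs = [segments[i] for i in folds.test_indices(fold)]
        train_segs = balance_classes(train_segs, seed=config.seed + fold)
        model = build_classifier(architecture_name, hyperparameters)
        train_classifier(model, train_segs, config)
        res = evaluate_fold(model, test_segs)
        report.confusion_matrices.append(res["confusion_matrix"])
        report.overall_tpr.append(res["overall_tpr"])
        report.ied_pr_curves.append(res["pr_curve"])
        report.ied_auprc.append(res["ied_auprc"])
    return report
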