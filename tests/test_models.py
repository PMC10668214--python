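"""Classifier contract: registry, probabilities, causality, training, CV."""

import numpy as np
import pytest

from iedscan.models import (
    CLASS_ORDER,
    RegistryError,
    TrainConfig,
    available_architectures,
    build_classifier,
    cross_validate,
    train_classifier,
)
from iedscan.models.base import PLACEHOLDER_ARCHITECTURES
from iedscan.segmentation import Segment
from iedscan.synthetic import SimConfig, pink_noise, spike_wave_template, _emg_burst

FAST_MLP = TrainConfig(epochs=8, seed=0)


def separable_segments(n_per_class: int, seed: int) -> list[Segment]:
    """Cleanly separable fixture: spike template vs EMG burst vs pink noise."""
    rng = np.random.default_rng(seed)
    segs = []
    template = spike_wave_template(256.0)
    for i in range(n_per_class):
        noise = 10.0 * pink_noise(256, rng)
        sig = noise.copy()
        i0 = rng.integers(40, 120)
        sig[i0 : i0 + len(template)] += rng.uniform(80, 150) * template
        segs.append(Segment(sig, "IED", ("s", "earlobe", "c", 0.0)))
        sig = noise + rng.uniform(40, 80) * np.pad(
            _emg_burst(128, 256.0, rng), (64, 64)
        )
        segs.append(Segment(sig, "artifact", ("s", "bipolar", "c", 0.0)))
        segs.append(Segment(10.0 * pink_noise(256, rng), "background", ("s", "earlobe", "c", 0.0)))
    return segs


class TestRegistry:
    def test_required_architectures_present(self):
        names = available_architectures()
        assert "tcn" in names and "mlp" in names

    def test_unknown_architecture_lists_available(self):
        with pytest.raises(RegistryError, match="tcn"):
            build_classifier("nonexistent")

    def test_placeholders_raise_not_implemented(self):
        for name in PLACEHOLDER_ARCHITECTURES:
            with pytest.raises(NotImplementedError):
                build_classifier(name)


class TestModelContract:
    @pytest.mark.parametrize("arch", ["tcn", "mlp"])
    def test_untrained_probabilities_normalized(self, arch, rng):
        model = build_classifier(arch)
        probs = model.predict_proba(rng.normal(size=(17, 256)))
        assert probs.shape == (17, 3)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_class_order_fixed(self):
        assert build_classifier("mlp").class_order == ("IED", "artifact", "background")

    def test_tcn_receptive_field_covers_window(self):
        model = build_classifier("tcn")
        assert model.receptive_field >= 256

    def test_tcn_causality(self, rng):
        """Zeroing samples at indices >= t leaves conv activations before t unchanged."""
        model = build_classifier("tcn")
        model.initialize(0)
        x = rng.normal(size=(2, 256))
        t = 100
        x_cut = x.copy()
        x_cut[:, t:] = 0.0
        full = model.conv_activations(x.astype(np.float32))
        cut = model.conv_activations(x_cut.astype(np.float32))
        assert np.allclose(full[:, :, :t], cut[:, :, :t], atol=1e-5)
        assert not np.allclose(full[:, :, t:], cut[:, :, t:], atol=1e-5)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_classifier("mlp")
        model.initialize(3)
        model.fitted = True
        model.save(tmp_path / "ck.npz", preprocessing_fingerprint="fp-test")
        loaded, meta = type(model).load(tmp_path / "ck.npz")
        assert meta["preprocessing_fingerprint"] == "fp-test"
        x = rng.normal(size=(5, 256))
        assert np.allclose(loaded.predict_proba(x), model.predict_proba(x))


class TestTraining:
    def test_loss_decreases(self):
        segs = separable_segments(40, seed=0)
        model = build_classifier("mlp")
        report = train_classifier(model, segs, FAST_MLP)
        assert report.epoch_losses[-1] < report.epoch_losses[0]
        assert model.fitted

    def test_memorizes_single_segment_per_class(self):
        segs = separable_segments(1, seed=1) * 20
        model = build_classifier("mlp")
        train_classifier(model, segs, TrainConfig(epochs=15, seed=0))
        x = np.stack([s.samples for s in segs[:3]])
        assert list(model.predict_label(x)) == [s.label for s in segs[:3]]

    def test_deterministic_under_seed(self):
        segs = separable_segments(20, seed=2)
        runs = []
        for _ in range(2):
            model = build_classifier("mlp")
            runs.append(train_classifier(model, segs, FAST_MLP).final_loss)
        assert runs[0] == pytest.approx(runs[1], rel=1e-4)

    def test_missing_class_rejected(self):
        segs = [s for s in separable_segments(10, seed=3) if s.label != "artifact"]
        with pytest.raises(Exception, match="artifact"):
            train_classifier(build_classifier("mlp"), segs, FAST_MLP)

    def test_tcn_separable_holdout_accuracy(self):
        """Spike vs EMG vs noise at 200/class: held-out accuracy >= 0.95."""
        train = separable_segments(200, seed=4)
        test = separable_segments(60, seed=5)
        model = build_classifier("tcn", {"n_filters": 8})
        train_classifier(model, train, TrainConfig(epochs=12, seed=0))
        x = np.stack([s.samples for s in test])
        y = np.array([s.label for s in test])
        acc = (model.predict_label(x) == y).mean()
        assert acc >= 0.95


class TestCrossValidate:
    def test_bookkeeping_on_tiny_dataset(self):
        segs = separable_segments(4, seed=6)
        # keep a single montage so every (label, montage) stratum has >= k members
        segs = [Segment(s.samples, s.label, ("s", "earlobe", "c", 0.0)) for s in segs]
        report = cross_validate("mlp", segs, k=2, config=TrainConfig(epochs=2, seed=0))
        assert len(report.confusion_matrices) == 2
        for fold, cm in enumerate(report.confusion_matrices):
            assert cm.sum() == 6
            assert np.all(cm >= 0)
        assert all(0.0 <= t <= 1.0 for t in report.overall_tpr)

    def test_shuffled_labels_give_chance_tpr(self):
        rng = np.random.default_rng(11)
        segs = separable_segments(30, seed=7)
        labels = [s.label for s in segs]
        rng.shuffle(labels)
        shuffled = [
            Segment(s.samples, lbl, ("s", "earlobe", "c", 0.0))
            for s, lbl in zip(segs, labels)
        ]
        report = cross_validate("mlp", shuffled, k=3, config=TrainConfig(epochs=5, seed=0))
        assert abs(np.mean(report.overall_tpr) - 1 / 3) < 0.1

    def test_separable_classes_score_highly(self):
        """Clean class separation: every fold's TPR >= 0.95, IED AUPRC >= 0.99."""
        segs = separable_segments(100, seed=8)
        report = cross_validate(
            "tcn", segs, k=3,
            config=TrainConfig(epochs=15, seed=0),
            hyperparameters={"n_filters": 8},
        )
        assert all(t >= 0.95 for t in report.overall_tpr)
        assert all(a >= 0.99 for a in report.ied_auprc)
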