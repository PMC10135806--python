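"""Loss, class weights, folds, early stopping, training, cross-validation."""

import math

import numpy as np
import pandas as pd
import pytest

from osteoseg.annotations import LabelMask
from osteoseg.network import NetworkConfig, labels_from_probabilities
from osteoseg.preprocess import ImageSample
from osteoseg.synthetic import SyntheticConfig, generate_samples
from osteoseg.train import (
    EarlyStopping,
    TrainingConfig,
    compute_class_weights,
    cross_validate,
    make_folds,
    train_model,
    weighted_categorical_cross_entropy,
)
from osteoseg.evaluate import confusion_from_masks


class TestLoss:
    def test_perfect_one_hot_is_near_zero(self):
        y = np.array([[0, 1], [2, 0]])
        p = np.zeros((3, 2, 2))
        np.put_along_axis(p, y[None], 1.0, axis=0)
        loss = weighted_categorical_cross_entropy(p, y, (1, 1, 1))
        assert 0 <= loss <= 1e-6

    def test_uniform_prediction_is_ln3(self):
        p = np.full((3, 4, 4), 1 / 3)
        y = np.random.default_rng(0).integers(0, 3, (4, 4))
        loss = weighted_categorical_cross_entropy(p, y, (1, 1, 1))
        assert loss == pytest.approx(math.log(3), abs=1e-9)

    def test_two_pixel_hand_computation(self):
        # true classes (1, 0); predicted true-class probabilities (0.5, 0.8);
        # weights (0.5, 2.0, 1.0) -> mean of {2.0*ln2, -0.5*ln0.8} = 0.74893
        p = np.zeros((3, 1, 2))
        p[:, 0, 0] = [0.3, 0.5, 0.2]
        p[:, 0, 1] = [0.8, 0.1, 0.1]
        y = np.array([[1, 0]])
        loss = weighted_categorical_cross_entropy(p, y, (0.5, 2.0, 1.0))
        expected = (2.0 * math.log(2) + 0.5 * (-math.log(0.8))) / 2
        assert loss == pytest.approx(expected, abs=1e-5)
        assert loss == pytest.approx(0.74893, abs=1e-5)

    def test_floor_keeps_loss_finite(self):
        p = np.zeros((3, 1, 1))
        p[0] = 1.0
        y = np.array([[2]])  # true class has probability 0
        loss = weighted_categorical_cross_entropy(p, y, (1, 1, 1))
        assert loss == pytest.approx(-math.log(1e-7), rel=1e-6)

    def test_shape_and_weight_validation(self):
        p = np.full((3, 2, 2), 1 / 3)
        with pytest.raises(ValueError, match="mismatch"):
            weighted_categorical_cross_entropy(p, np.zeros((3, 3), int),
                                               (1, 1, 1))
        with pytest.raises(ValueError, match="positive"):
            weighted_categorical_cross_entropy(p, np.zeros((2, 2), int),
                                               (1, 0, 1))


class TestClassWeights:
    def test_equal_counts_give_unit_weights(self):
        grid = np.repeat(np.array([[0, 1, 2]]), 3, axis=0).astype(np.uint8)
        np.testing.assert_allclose(compute_class_weights([LabelMask(grid)]),
                                   [1, 1, 1])

    def test_hand_computed_inverse_frequencies(self):
        # frequencies (0.5, 0.25, 0.25) -> inverses (2, 4, 4) -> mean-1
        # rescale -> (0.6, 1.2, 1.2)
        grid = np.array([[0, 0, 1, 2]], dtype=np.uint8)
        np.testing.assert_allclose(compute_class_weights([LabelMask(grid)]),
                                   [0.6, 1.2, 1.2])

    def test_absent_class_is_an_error(self):
        grid = np.array([[0, 1, 0, 1]], dtype=np.uint8)
        with pytest.raises(ValueError, match="intact"):
            compute_class_weights([LabelMask(grid)])


class TestFolds:
    def test_99_images_into_10_folds(self):
        ids = [f"img{i}" for i in range(99)]
        split = make_folds(ids, k=10, seed=0)
        sizes = sorted(len(f) for f in split.folds)
        assert sizes == [9] + [10] * 9

    def test_partition_property(self):
        ids = [f"img{i}" for i in range(25)]
        split = make_folds(ids, k=4, seed=1)
        flat = [i for f in split.folds for i in f]
        assert sorted(flat) == sorted(ids)

    def test_seed_determinism(self):
        ids = list(range(30))
        a = make_folds(ids, k=5, seed=3)
        b = make_folds(ids, k=5, seed=3)
        assert a.folds == b.folds
        c = make_folds(ids, k=5, seed=4)
        assert a.folds != c.folds

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds(list(range(5)), k=10)


class TestEarlyStopping:
    def test_strictly_worsening_stops_at_patience_plus_one(self):
        stopper = EarlyStopping(patience=25)
        weights = [np.zeros(1)]
        stopped_at = None
        for epoch in range(1, 100):
            if stopper.update(1.0 + 0.1 * epoch, weights, epoch):
                stopped_at = epoch
                break
        assert stopped_at == 26
        assert stopper.best_epoch == 1

    def test_best_weights_restored_from_best_epoch(self):
        stopper = EarlyStopping(patience=3)
        losses = [0.5, 0.3, 0.4, 0.35, 0.45, 0.5]
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(loss, [np.array([float(epoch)])], epoch):
                break
        assert stopper.best_epoch == 2
        assert stopper.best_weights[0][0] == 2.0
        assert stopper.best_loss == 0.3


def tiny_samples(n=6, size=64, seed=0):
    cfg = SyntheticConfig(image_size=size, n_intact=(1, 3), n_fragment=(1, 2),
                          osteon_radius=(4, 9))
    return generate_samples(n, cfg, seed=seed)


class TestTrainModel:
    NET = NetworkConfig(input_size=64, depth=3, base_filters=4)

    def test_loss_descends_on_learnable_data(self):
        samples = tiny_samples(6)
        cfg = TrainingConfig(max_epochs=12, patience=12, seed=0,
                             validation_fraction=0.2)
        _, log = train_model(samples, cfg, self.NET)
        h = log.history
        assert h["train_loss"].iloc[-3:].mean() < h["train_loss"].iloc[0]

    def test_same_seed_same_first_epoch_loss(self):
        samples = tiny_samples(5)
        cfg = TrainingConfig(max_epochs=2, patience=5, seed=11)
        _, log1 = train_model(samples, cfg, self.NET)
        _, log2 = train_model(samples, cfg, self.NET)
        assert log1.history["train_loss"].iloc[0] == \
               log2.history["train_loss"].iloc[0]
        pd.testing.assert_frame_equal(log1.history, log2.history)

    def test_early_stop_bounds_epochs_and_restores_best(self):
        samples = tiny_samples(6)
        cfg = TrainingConfig(max_epochs=30, patience=2, seed=1,
                             learning_rate=0.5)  # large lr forces divergence
        _, log = train_model(samples, cfg, self.NET)
        h = log.history
        assert len(h) < 30
        assert log.best_epoch == \
               int(h.loc[h["val_loss"].idxmin(), "epoch"])

    def test_empty_or_tiny_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_model([], TrainingConfig(), self.NET)
        with pytest.raises(ValueError, match=">= 2"):
            train_model(tiny_samples(2), TrainingConfig(), self.NET)


class TestCrossValidate:
    def test_every_sample_tested_once_and_matrix_normalized(self):
        samples = tiny_samples(9)

        def oracle(train, test, seed):
            # deterministic image-thresholding stand-in for training
            return [
                LabelMask((s.image < 0.25).astype(np.uint8) * 2) for s in test
            ]

        result = cross_validate(samples, k=3, seed=5, predict_fn=oracle)
        tested = [i for fold in result.folds.folds for i in fold]
        assert sorted(tested) == sorted(s.sample_id for s in samples)
        assert result.normalized.counts.sum() == pytest.approx(1.0, abs=1e-9)
        assert result.confusion.total == 9 * 64 * 64

    def test_oracle_substitution_equals_whole_set_matrix(self):
        samples = tiny_samples(8, seed=3)

        def predictor(image):
            return LabelMask((image < 0.25).astype(np.uint8) * 2)

        result = cross_validate(
            samples, k=4, seed=2,
            predict_fn=lambda tr, te, s: [predictor(x.image) for x in te],
        )
        direct = confusion_from_masks(
            [s.mask for s in samples],
            [predictor(s.image) for s in samples],
        )
        np.testing.assert_array_equal(result.confusion.counts, direct.counts)

    def test_fold_order_permutation_invariance(self):
        samples = tiny_samples(6, seed=4)
        pred = lambda tr, te, s: [
            LabelMask(np.zeros_like(x.mask.grid)) for x in te
        ]
        a = cross_validate(samples, k=3, seed=7, predict_fn=pred)
        b = cross_validate(list(reversed(samples)), k=3, seed=7,
                           predict_fn=pred)
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)
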