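"""Splitting, early stopping, and the training harness on tiny problems."""

import numpy as np
import pytest

from dicomanno.train import (
    EarlyStopping,
    TrainingConfig,
    grid_search_cv,
    level_accuracy,
    stratified_kfold_split,
    train_classifier,
)
from dicomanno.synthetic import PhantomSpec, generate_phantom
from dicomanno.preprocess import resize_image


def _tiny_config(**kw):
    defaults = dict(
        image_size=16, channels=(4, 8), max_epochs=4, patience=2, batch=16, lr=1e-2, seed=0
    )
    defaults.update(kw)
    return TrainingConfig(**defaults)


def _phantom_set(codes, n_per_class, size=16, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for code in codes:
        for _ in range(n_per_class):
            img = generate_phantom(PhantomSpec(body_part=code, size=64), rng)
            X.append(resize_image(img, size))
            y.append(code)
    return np.array(X), np.array(y)


class TestStratifiedKFold:
    def test_balanced_two_class_split(self):
        labels = np.array([0] * 50 + [1] * 50)
        fa = stratified_kfold_split(labels, k=5, seed=0)
        for f in range(5):
            ids = fa.fold_ids(f)
            assert len(ids) == 20
            assert sum(labels[i] == 0 for i in ids) == 10

    def test_folds_partition_all_ids(self):
        labels = np.random.default_rng(0).integers(0, 4, 83)
        fa = stratified_kfold_split(labels, k=5, seed=1)
        all_ids = sorted(fa.fold_of)
        assert all_ids == list(range(83))
        assert set(fa.fold_of.values()) <= set(range(5))

    def test_per_class_fold_deviation_at_most_one(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            labels = rng.integers(0, 6, 200)
            fa = stratified_kfold_split(labels, k=5, seed=trial)
            for c in np.unique(labels):
                counts = [
                    sum(labels[i] == c for i in fa.fold_ids(f)) for f in range(5)
                ]
                assert max(counts) - min(counts) <= 1

    def test_rare_class_warns(self):
        labels = np.array([0] * 20 + [1] * 3)
        with pytest.warns(UserWarning, match="members"):
            fa = stratified_kfold_split(labels, k=5, seed=0)
        assert len(fa.fold_of) == 23

    def test_seed_changes_assignment(self):
        labels = np.array([0, 1] * 25)
        a = stratified_kfold_split(labels, k=5, seed=0).fold_of
        b = stratified_kfold_split(labels, k=5, seed=1).fold_of
        assert a != b


class TestEarlyStopping:
    def test_strictly_worsening_stops_after_patience(self):
        es = EarlyStopping(patience=8)
        stops = [es.update(e, 1.0 + e) for e in range(20)]
        assert stops.index(True) == 8  # epoch 0 best + 8 stale epochs
        assert es.best_epoch == 0

    def test_best_epoch_is_minimum(self):
        es = EarlyStopping(patience=3)
        losses = [5, 4, 6, 3, 4, 5, 6]
        for e, v in enumerate(losses):
            if es.update(e, v):
                break
        assert es.best_epoch == 3
        assert es.best == 3

    def test_improvement_resets_counter(self):
        es = EarlyStopping(patience=2)
        assert not es.update(0, 1.0)
        assert not es.update(1, 2.0)
        assert not es.update(2, 0.5)
        assert not es.update(3, 0.9)
        assert es.update(4, 0.9)


class TestTrainClassifier:
    CODES = [51185008, 89546000, 85562004]

    def test_same_seed_same_weights(self):
        X, y = _phantom_set(self.CODES, 10)
        cfg = _tiny_config()
        t1 = train_classifier(X, y, self.CODES, cfg)
        t2 = train_classifier(X, y, self.CODES, cfg)
        assert t1.checksum() == t2.checksum()
        assert [h["val_loss"] for h in t1.history] == [h["val_loss"] for h in t2.history]

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_classifier(np.empty((0, 16, 16)), np.array([]), self.CODES, _tiny_config())

    def test_label_outside_vocabulary_rejected(self):
        X, _ = _phantom_set(self.CODES[:1], 4)
        with pytest.raises(ValueError, match="outside"):
            train_classifier(X, np.array([42] * 4), self.CODES, _tiny_config())

    def test_history_bounded_and_best_epoch_is_minimum(self):
        X, y = _phantom_set(self.CODES, 8)
        trained = train_classifier(X, y, self.CODES, _tiny_config())
        assert len(trained.history) <= 4
        losses = [h["val_loss"] for h in trained.history]
        assert trained.history[trained.best_epoch]["val_loss"] == min(losses)

    def test_separable_phantoms_reach_high_accuracy(self, hier):
        # parameter-recovery: 5 distinct motifs must be learned nearly perfectly
        codes = [51185008, 89546000, 85562004, 72696002, 12921003]
        X, y = _phantom_set(codes, 20, size=32, seed=1)
        cfg = TrainingConfig(image_size=32, channels=(8, 16, 32), max_epochs=30,
                             patience=8, batch=32, lr=1e-3, seed=0)
        trained = train_classifier(X, y, codes, cfg, hier=hier)
        best = trained.history[trained.best_epoch]
        assert best["val_accuracy"] >= 0.9

    def test_hierarchical_loss_training_and_level_accuracy_ordering(self, hier):
        codes = [85562004, 12921003, 56459004]  # hand / pelvis / foot
        X, y = _phantom_set(codes, 12, seed=2)
        cfg = _tiny_config(loss="hierarchical", max_epochs=6, patience=3)
        trained = train_classifier(X, y, codes, cfg, hier=hier)
        leaf = level_accuracy(trained, X, y, hier, level=3)
        lvl1 = level_accuracy(trained, X, y, hier, level=1)
        assert lvl1 >= leaf

    def test_multilabel_task_trains_and_predicts_indicators(self, hier):
        codes = [85562004, 12921003]
        X, y = _phantom_set(codes, 10)
        Y = np.zeros((len(y), 2))
        Y[y == codes[0], 0] = 1
        Y[y == codes[1], 1] = 1
        cfg = _tiny_config(task="visible", loss="hierarchical", max_epochs=6, patience=3)
        trained = train_classifier(X, Y, codes, cfg, hier=hier)
        pred = trained.predict(X)
        assert pred.shape == Y.shape
        assert set(np.unique(pred)) <= {0, 1}

    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ValueError):
            TrainingConfig(max_epochs=8, patience=8)


class TestGridSearch:
    CODES = [51185008, 85562004]

    def test_single_config_grid_returns_it(self):
        X, y = _phantom_set(self.CODES, 10)
        cfg = _tiny_config(max_epochs=2, patience=1)
        best, table = grid_search_cv(X, y, self.CODES, [cfg], k=3)
        assert best is cfg
        assert len(table) == 1

    def test_label_destroying_augmentation_loses(self):
        X, y = _phantom_set(self.CODES, 12)

        def destroy(batch, rng):
            return rng.random(batch.shape)  # replaces content with noise

        good = _tiny_config(max_epochs=3, patience=2)
        bad = _tiny_config(max_epochs=3, patience=2, batch_transform=destroy)
        best, table = grid_search_cv(X, y, self.CODES, [bad, good], k=3)
        assert best is good
        assert table.loc[1, "mean_accuracy"] >= table.loc[0, "mean_accuracy"]

    def test_table_shape(self):
        X, y = _phantom_set(self.CODES, 8)
        cfgs = [_tiny_config(max_epochs=2, patience=1, lr=lr) for lr in (1e-2, 1e-3)]
        _, table = grid_search_cv(X, y, self.CODES, cfgs, k=3)
        assert len(table) == 2
        assert {"fold0_accuracy", "fold1_accuracy", "fold2_accuracy", "mean_accuracy"} <= set(table.columns)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_cv(np.ones((4, 16, 16)), np.zeros(4), [0], [], k=2)
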