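"""Split bookkeeping, loss protocol and the optimization loop."""

import numpy as np
import pytest

from ramandense.io import AxisGrid, SpectraDataset
from ramandense.nn.network import DenseNetConfig, build_network
from ramandense.synth import PostureModel, generate_dataset
from ramandense.training import (
    SplitIndices,
    TrainConfig,
    stratified_split,
    train_model,
)

EASY_POSTURES = PostureModel((0.3, 0.3), (0.25, 0.3), (0.05, 0.3))


def labels_only_dataset(class_sizes: dict[str, int], postures=None,
                        n_points: int = 8) -> SpectraDataset:
    """A dataset whose spectra are blank: only the label/posture bookkeeping
    matters for split tests."""
    labels = [name for name, n in class_sizes.items() for _ in range(n)]
    grid = AxisGrid(0.0, 1.0, n_points)
    return SpectraDataset(
        grid,
        np.zeros((len(labels), n_points), dtype=np.float32),
        np.asarray(labels),
        list(class_sizes),
        None if postures is None else np.asarray(postures),
    )


class TestStratifiedSplit:
    def test_1600_spectra_split_56_14_30(self):
        # 32 classes x 50, postures in near-equal thirds (17/17/16)
        labels, postures = [], []
        for c in range(32):
            for posture, n in zip(("upright", "side", "bottom"), (17, 17, 16)):
                labels += [f"c{c}"] * n
                postures += [posture] * n
        ds = labels_only_dataset(
            {f"c{c}": 50 for c in range(32)},
        )
        ds = SpectraDataset(ds.grid, ds.intensities, np.asarray(labels),
                            [f"c{c}" for c in range(32)], np.asarray(postures))
        s = stratified_split(ds, TrainConfig())
        assert (len(s.train), len(s.val), len(s.test)) == (896, 224, 480)

    def test_seeded_determinism(self, small_dataset):
        a = stratified_split(small_dataset, rng_seed=5)
        b = stratified_split(small_dataset, rng_seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.val, b.val)
        np.testing.assert_array_equal(a.test, b.test)

    def test_subsets_disjoint_and_cover(self, small_dataset):
        s = stratified_split(small_dataset, rng_seed=1)
        joined = np.concatenate([s.train, s.val, s.test])
        assert len(np.unique(joined)) == len(joined) == len(small_dataset)

    def test_every_class_in_every_subset(self):
        ds = labels_only_dataset({f"c{k}": 30 for k in range(8)})
        s = stratified_split(ds, rng_seed=2)
        for subset in (s.train, s.val, s.test):
            assert set(ds.labels[subset]) == set(ds.class_names)

    def test_per_stratum_proportions_respected(self):
        ds = labels_only_dataset({"a": 100, "b": 100})
        s = stratified_split(ds, rng_seed=0)
        for name in ("a", "b"):
            in_test = (ds.labels[s.test] == name).sum()
            assert in_test == 30  # 30% of 100 exactly

    def test_missing_class_rejected(self):
        ds = labels_only_dataset({"a": 10, "b": 10})
        broken = SpectraDataset(ds.grid, ds.intensities, ds.labels,
                                ["a", "b", "ghost"], None)
        with pytest.raises(ValueError, match="ghost"):
            stratified_split(broken)

    def test_overlapping_indices_rejected(self):
        with pytest.raises(ValueError):
            SplitIndices(np.array([0, 1]), np.array([1, 2]), np.array([3]))


class TestTrainConfig:
    def test_protocol_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 1e-4
        assert cfg.batch_size == 32
        assert cfg.max_epochs == 200
        assert cfg.patience == 20
        assert (cfg.train_fraction, cfg.val_fraction_of_train) == (0.7, 0.2)

    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(patience=10, max_epochs=10)


@pytest.fixture(scope="module")
def easy_task():
    grid = AxisGrid(170.0, 3200.0, 259)
    ds = generate_dataset(4, 24, rng_seed=5, grid=grid,
                          posture_model=EASY_POSTURES)
    return ds


def tiny_model(n_classes, input_length, seed):
    cfg = DenseNetConfig.reduced(
        n_classes=n_classes, input_length=input_length,
        embedding_channels=(2, 4, 8), base_features=8, head_units=32,
    )
    return build_network(cfg, rng_seed=seed)


class TestTrainModel:
    def test_early_stop_after_patience_with_constant_monitor(self, easy_task):
        cfg = TrainConfig(max_epochs=50, patience=4, rng_seed=0)
        splits = stratified_split(easy_task, cfg)
        model = tiny_model(4, 259, seed=0)
        model, hist = train_model(
            model, easy_task, splits, cfg, monitor_fn=lambda m, e, h: 0.5
        )
        # first epoch improves over -inf, then `patience` stale epochs
        assert len(hist) == cfg.patience + 1

    def test_history_bounded_by_max_epochs(self, easy_task):
        cfg = TrainConfig(max_epochs=3, patience=2, rng_seed=0)
        splits = stratified_split(easy_task, cfg)
        model = tiny_model(4, 259, seed=1)
        _, hist = train_model(model, easy_task, splits, cfg)
        assert len(hist) <= 3
        assert hist.column("epoch") == sorted(hist.column("epoch"))

    def test_empty_training_split_rejected(self, easy_task):
        splits = stratified_split(easy_task, rng_seed=0)
        empty = SplitIndices(np.array([], dtype=int), splits.val, splits.test)
        with pytest.raises(ValueError, match="empty"):
            train_model(tiny_model(4, 259, 0), easy_task, empty)

    def test_class_count_mismatch_rejected(self, easy_task):
        splits = stratified_split(easy_task, rng_seed=0)
        with pytest.raises(ValueError, match="classes"):
            train_model(tiny_model(6, 259, 0), easy_task, splits)

    def test_loss_decreases_on_easy_task(self, easy_task):
        # epoch-5 training loss below epoch-1, averaged over 3 seeds
        first, fifth = [], []
        for seed in range(3):
            cfg = TrainConfig(max_epochs=5, patience=4, rng_seed=seed)
            splits = stratified_split(easy_task, cfg)
            _, hist = train_model(tiny_model(4, 259, seed), easy_task, splits, cfg)
            losses = hist.column("train_loss")
            first.append(losses[0])
            fifth.append(losses[4])
        assert np.mean(fifth) < np.mean(first)

    def test_easy_task_reaches_high_validation_accuracy(self, easy_task):
        cfg = TrainConfig(max_epochs=30, patience=8, rng_seed=7)
        splits = stratified_split(easy_task, cfg)
        model, hist = train_model(tiny_model(4, 259, 7), easy_task, splits, cfg)
        assert max(hist.column("val_accuracy")) >= 0.95

    def test_history_carries_epoch_metrics(self, easy_task):
        cfg = TrainConfig(max_epochs=2, patience=1, rng_seed=0)
        splits = stratified_split(easy_task, cfg)
        _, hist = train_model(tiny_model(4, 259, 2), easy_task, splits, cfg)
        rec = hist.records[0]
        for key in ("train_loss", "train_recall", "train_precision", "train_auc",
                    "val_loss", "val_recall", "val_precision", "val_auc"):
            assert key in rec and rec[key] is not None
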