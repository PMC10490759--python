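"""Training protocol: stratified splits, loss, optimization, early stopping.

The protocol is fixed by the study design: a 70/30 train/test split
stratified by both class and detection posture, with 20% of the training
portion held out for validation (56:14:30 overall); categorical
cross-entropy minimized with Adam (learning rate 1e-4, batch 32); at most
200 epochs with early stopping once validation accuracy fails to improve for
20 consecutive epochs, restoring the best-epoch weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io import SpectraDataset
from .nn.losses import categorical_cross_entropy, softmax_cross_entropy_with_logits
from .nn.network import Network
from .nn.optim import Adam

__all__ = [
    "TrainConfig",
    "SplitIndices",
    "TrainHistory",
    "stratified_split",
    "one_hot",
    "categorical_cross_entropy",
    "train_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer, batching and early-stopping settings.

    ``rng_seed`` governs split shuffling and minibatch order; weight
    initialization is seeded separately when the model is built.
    """

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    train_fraction: float = 0.7
    val_fraction_of_train: float = 0.2
    rng_seed: int = 0
    monitor: str = "val_accuracy"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0 < self.val_fraction_of_train < 1:
            raise ValueError("val_fraction_of_train must lie in (0, 1)")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("patience must be positive and below max_epochs")


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/validation/test index sets covering a dataset."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        t, v, s = (np.asarray(a) for a in (self.train, self.val, self.test))
        all_idx = np.concatenate([t, v, s])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split subsets overlap")
        object.__setattr__(self, "train", t)
        object.__setattr__(self, "val", v)
        object.__setattr__(self, "test", s)


def _allocate_largest_remainder(sizes: np.ndarray, fraction: float) -> np.ndarray:
    """Per-stratum counts at ``fraction`` summing exactly to the rounded
    global target, floor first then +1 to the largest fractional remainders
    (ties broken by stratum order)."""
    quotas = sizes * fraction
    base = np.floor(quotas).astype(int)
    total = int(round(sizes.sum() * fraction))
    deficit = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for i in order[:max(deficit, 0)]:
        base[i] += 1
    return base


def stratified_split(
    dataset: SpectraDataset,
    config: TrainConfig | None = None,
    rng_seed: int | None = None,
) -> SplitIndices:
    """Split by (class, posture) strata at the configured fractions.

    Per stratum, a ``1 - train_fraction`` share goes to test and a
    ``val_fraction_of_train`` share of the remainder to validation, with
    largest-remainder rounding so the global 56:14:30 proportions are exact
    whenever they can be. If any (class, posture) cell has fewer than 3
    members — or postures are unrecorded — stratification falls back to class
    only. Deterministic per seed.
    """
    config = config if config is not None else TrainConfig()
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)

    labels = np.asarray([str(l) for l in dataset.labels])
    counts = {name: int((labels == name).sum()) for name in dataset.class_names}
    missing = [name for name, c in counts.items() if c == 0]
    if missing:
        raise ValueError(f"classes absent from the dataset: {missing}")

    if dataset.postures is not None:
        postures = np.asarray([str(p) for p in dataset.postures])
        strata_keys = np.array([f"{l}\x00{p}" for l, p in zip(labels, postures)])
        _, cell_counts = np.unique(strata_keys, return_counts=True)
        if cell_counts.min() < 3:
            strata_keys = labels  # cells too small: class-only strata
    else:
        strata_keys = labels

    uniq = list(dict.fromkeys(strata_keys))  # first-appearance order
    members = [np.flatnonzero(strata_keys == key) for key in uniq]
    sizes = np.array([len(m) for m in members])

    n_test = _allocate_largest_remainder(sizes, 1.0 - config.train_fraction)
    train_parts, test_parts = [], []
    for m, t in zip(members, n_test):
        perm = rng.permutation(m)
        test_parts.append(perm[:t])
        train_parts.append(perm[t:])

    train_sizes = sizes - n_test
    n_val = _allocate_largest_remainder(train_sizes, config.val_fraction_of_train)
    val_parts, final_train = [], []
    for m, v in zip(train_parts, n_val):
        val_parts.append(m[:v])
        final_train.append(m[v:])

    return SplitIndices(
        np.sort(np.concatenate(final_train)),
        np.sort(np.concatenate(val_parts)),
        np.sort(np.concatenate(test_parts)),
    )


def one_hot(indices: Sequence[int], n_classes: int) -> np.ndarray:
    idx = np.asarray(indices, dtype=int)
    out = np.zeros((len(idx), n_classes), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


@dataclass
class TrainHistory:
    """Per-epoch metrics on the training and validation splits."""

    records: list[dict] = field(default_factory=list)

    def append(self, **metrics) -> None:
        self.records.append(dict(metrics))

    def __len__(self) -> int:
        return len(self.records)

    def column(self, name: str) -> list:
        return [r.get(name) for r in self.records]

    @property
    def best_epoch(self) -> int:
        vals = self.column("val_accuracy")
        return int(np.argmax([v if v is not None else -np.inf for v in vals]))


def train_model(
    model: Network,
    dataset: SpectraDataset,
    splits: SplitIndices,
    config: TrainConfig | None = None,
    monitor_fn: Callable[[Network, int, TrainHistory], float] | None = None,
    verbose: bool = False,
    log_fn: Callable[[str], None] | None = None,
) -> tuple[Network, TrainHistory]:
    """Mini-batch Adam on categorical cross-entropy with early stopping.

    Stops at ``max_epochs`` or once the monitored validation accuracy has
    failed to strictly improve for ``patience`` consecutive epochs, and
    restores the weights of the best-monitor epoch. Training-split metrics
    are accumulated over the epoch's minibatches (as the pass runs);
    validation metrics come from a full inference pass per epoch.

    ``monitor_fn`` overrides the monitored quantity (used for protocol
    tests); it receives the model, epoch index and history so far.
    """
    from .evaluation import epoch_metrics  # local import avoids a cycle

    config = config if config is not None else TrainConfig()
    if len(splits.train) == 0:
        raise ValueError("empty training split")
    if model.n_classes != dataset.n_classes:
        raise ValueError(
            f"model expects {model.n_classes} classes, dataset has {dataset.n_classes}"
        )

    x = np.asarray(dataset.intensities, dtype=np.float32)[:, :, None]
    y_idx = dataset.label_indices
    y = one_hot(y_idx, dataset.n_classes)

    rng = np.random.default_rng(config.rng_seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()

    best_monitor = -np.inf
    best_state = None
    stale = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(splits.train)
        batch_losses, probs_chunks, truth_chunks = [], [], []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, probs, dlogits = softmax_cross_entropy_with_logits(logits, y[idx])
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            batch_losses.append(loss)
            probs_chunks.append(probs)
            truth_chunks.append(y_idx[idx])

        train_probs = np.vstack(probs_chunks)
        train_truth = np.concatenate(truth_chunks)
        train_loss = float(np.mean(batch_losses))
        train_acc = float((train_probs.argmax(axis=1) == train_truth).mean())
        t_recall, t_precision, t_auc = epoch_metrics(
            train_truth, train_probs, n_classes=dataset.n_classes
        )

        val_probs = model.predict_proba(x[splits.val])
        val_truth = y_idx[splits.val]
        val_loss = categorical_cross_entropy(y[splits.val], val_probs)
        val_acc = float((val_probs.argmax(axis=1) == val_truth).mean())
        v_recall, v_precision, v_auc = epoch_metrics(
            val_truth, val_probs, n_classes=dataset.n_classes
        )

        history.append(
            epoch=epoch,
            train_loss=train_loss, train_accuracy=train_acc,
            train_recall=t_recall, train_precision=t_precision, train_auc=t_auc,
            val_loss=val_loss, val_accuracy=val_acc,
            val_recall=v_recall, val_precision=v_precision, val_auc=v_auc,
        )
        if verbose or log_fn is not None:
            line = (
                f"epoch {epoch + 1:3d}  loss {train_loss:.4f}  acc {train_acc:.4f}  "
                f"val_loss {val_loss:.4f}  val_acc {val_acc:.4f}"
            )
            (log_fn or print)(line)

        monitor = (
            monitor_fn(model, epoch, history) if monitor_fn is not None else val_acc
        )
        if monitor > best_monitor:
            best_monitor = monitor
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best_state is not None:
        model.set_state(best_state)
    return model, history
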