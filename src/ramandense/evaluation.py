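"""Prediction, confusion matrices and the repeated-experiment protocol.

Because weight initialization and the dataset split are both random, a
single train/test cycle is not a stable measurement. The protocol therefore
repeats the whole cycle (fresh split seed, fresh initialization seed per
run), pools every run's test predictions into one *weighted accuracy*
(total correct / total predicted across runs), and counts runs whose test
accuracy falls below 20% as *errors* — failed convergences, typically from
vanished or exploded gradients — reported as an error rate over the runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from .io import SpectraDataset
from .nn.network import Network, PredictionResult
from .training import SplitIndices, TrainConfig, stratified_split, train_model

__all__ = [
    "ERROR_ACCURACY_THRESHOLD",
    "RunResult",
    "ExperimentSummary",
    "predict",
    "confusion_matrix",
    "is_error_run",
    "weighted_accuracy",
    "repeated_experiments",
    "epoch_metrics",
]

#: A run below this test accuracy is counted as a failed training (an
#: "error"): the model never converged, so its outputs are noise.
ERROR_ACCURACY_THRESHOLD = 0.20


def predict(model: Network, spectra: SpectraDataset | np.ndarray,
            batch_size: int = 64) -> list[PredictionResult]:
    """Per-spectrum class probabilities and argmax classes."""
    x = spectra.intensities if isinstance(spectra, SpectraDataset) else np.asarray(spectra)
    return model.predict(x, batch_size=batch_size)


def confusion_matrix(
    truths: Sequence, predictions: Sequence, class_names: Sequence[str]
) -> np.ndarray:
    """Count matrix, rows = true class, columns = predicted class."""
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions differ in length")
    index = {str(name): i for i, name in enumerate(class_names)}
    n = len(class_names)
    out = np.zeros((n, n), dtype=int)
    for t, p in zip(truths, predictions):
        try:
            out[index[str(t)], index[str(p)]] += 1
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in class_names") from None
    return out


def is_error_run(accuracy: float) -> bool:
    """True iff the run failed to converge (test accuracy strictly below 20%)."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    return accuracy < ERROR_ACCURACY_THRESHOLD


@dataclass
class RunResult:
    """One train/test cycle: test accuracy and confusion matrix."""

    accuracy: float
    confusion: np.ndarray
    n_test: int
    is_error: bool = field(init=False)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        self.is_error = is_error_run(self.accuracy)

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.confusion))


def weighted_accuracy(runs: Sequence[RunResult], include_errors: bool = True) -> float:
    """Pooled correct / pooled predictions across runs."""
    pool = [r for r in runs if include_errors or not r.is_error]
    if not pool:
        return float("nan")
    return sum(r.n_correct for r in pool) / sum(r.n_test for r in pool)


@dataclass
class ExperimentSummary:
    """Pooled outcome of repeated train/test cycles."""

    runs: list[RunResult]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.runs])

    @property
    def weighted_accuracy(self) -> float:
        return weighted_accuracy(self.runs, include_errors=True)

    @property
    def weighted_accuracy_excluding_errors(self) -> float:
        return weighted_accuracy(self.runs, include_errors=False)

    @property
    def error_rate(self) -> float:
        return sum(r.is_error for r in self.runs) / self.n_runs

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    def as_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "accuracies": self.accuracies.tolist(),
            "weighted_accuracy": self.weighted_accuracy,
            "weighted_accuracy_excluding_errors": self.weighted_accuracy_excluding_errors,
            "error_rate": self.error_rate,
            "mean_accuracy": self.mean_accuracy,
        }


def evaluate_run(model: Network, dataset: SpectraDataset,
                 test_indices: np.ndarray) -> RunResult:
    """Test-split accuracy and confusion matrix for a trained model."""
    test = dataset.subset(test_indices)
    probs = model.predict_proba(test.intensities)
    pred_idx = probs.argmax(axis=1)
    preds = [dataset.class_names[k] for k in pred_idx]
    conf = confusion_matrix(test.labels, preds, dataset.class_names)
    acc = float(np.trace(conf) / conf.sum())
    return RunResult(accuracy=acc, confusion=conf, n_test=len(test))


def run_seeds(seed_base: int, run: int) -> tuple[int, int]:
    """Derive independent (split, init) seeds for one run, both < 2^31."""
    state = np.random.SeedSequence([seed_base, run]).generate_state(2)
    return int(state[0]) % 2**31, int(state[1]) % 2**31


def repeated_experiments(
    dataset: SpectraDataset,
    model_builder: Callable[[int], Network],
    train_config: TrainConfig | None = None,
    n_runs: int = 50,
    seed_base: int = 0,
    log_fn: Callable[[str], None] | None = None,
) -> ExperimentSummary:
    """Repeat train/test cycles with fresh split and initialization seeds.

    Run *r* derives a split seed and a weight-initialization seed from
    ``(seed_base, r)``; the dataset itself is fixed. A run that raises during
    training is recorded as an error run with accuracy 0.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    train_config = train_config if train_config is not None else TrainConfig()
    runs: list[RunResult] = []
    for r in range(n_runs):
        split_seed, init_seed = run_seeds(seed_base, r)
        splits = stratified_split(dataset, train_config, rng_seed=split_seed)
        model = model_builder(init_seed)
        cfg = TrainConfig(**{**train_config.__dict__, "rng_seed": split_seed})
        try:
            model, _ = train_model(model, dataset, splits, cfg)
            result = evaluate_run(model, dataset, splits.test)
        except Exception:  # a failed training counts as an error run
            n = len(splits.test)
            result = RunResult(
                accuracy=0.0,
                confusion=np.zeros((dataset.n_classes, dataset.n_classes), dtype=int),
                n_test=n,
            )
        runs.append(result)
        if log_fn is not None:
            log_fn(
                f"run {r + 1}/{n_runs}: accuracy {result.accuracy:.4f}"
                + (" (error)" if result.is_error else "")
            )
    return ExperimentSummary(runs)


def epoch_metrics(
    truths: Sequence[int],
    probability_matrix: np.ndarray,
    n_classes: int | None = None,
    average: str = "micro",
) -> tuple[float, float, float | None]:
    """Micro-averaged (recall, precision, AUC) of one epoch's predictions.

    Precision and recall use the 0.5 one-vs-rest threshold on the class
    probabilities; AUC is the micro one-vs-rest rank statistic. With a
    single-class truth set the AUC is undefined and returned as ``None``.
    """
    t = np.asarray(truths, dtype=int)
    p = np.asarray(probability_matrix, dtype=float)
    if p.ndim != 2 or len(t) != len(p):
        raise ValueError("probability matrix and truths disagree")
    k = n_classes if n_classes is not None else p.shape[1]
    onehot = np.zeros((len(t), k))
    onehot[np.arange(len(t)), t] = 1.0
    hard = (p >= 0.5).astype(int)
    recall = float(recall_score(onehot.ravel(), hard.ravel(), zero_division=0.0))
    precision = float(precision_score(onehot.ravel(), hard.ravel(), zero_division=0.0))
    if len(np.unique(t)) < 2:
        auc = None  # one-vs-rest ranking is undefined with a single truth class
    else:
        try:
            auc = float(roc_auc_score(onehot.ravel(), p.ravel()))
        except ValueError:
            auc = None
    return recall, precision, auc
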