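"""Leave-one-subject-out training and evaluation.

Every fold holds out all trials of one subject, trains on the rest with
Adam under an exponentially decaying learning rate, and reports the mean
test accuracy of the last ``metric_window`` epochs (the convergence-plateau
convention), plus the confusion matrix at the final epoch.  A run summary
aggregates fold accuracies into mean/population-std and a row-normalized
confusion matrix in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Adam
from .features import BandFeatureTensor, CLASS_NAMES
from .graph import ElectrodeLayout
from .model import ModelConfig, SgcSrmModel

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "FoldResult",
    "RunSummary",
    "loso_folds",
    "split_tensor",
    "train_fold",
    "run_loso",
    "summarize_run",
    "ablate",
    "ABLATION_SWITCHES",
    "band_sweep",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer schedule: Adam, lr decaying as lr0 * decay**epoch."""

    lr0: float = 0.001
    decay: float = 0.96
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    metric_window: int = 10

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must lie in (0, 1]")
        if self.epochs < self.metric_window:
            raise ValueError("epochs must be >= metric_window")

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.decay**epoch


@dataclass
class FoldResult:
    """Outcome of one held-out subject."""

    held_out_subject: str
    per_epoch_test_accuracy: list[float]
    fold_accuracy: float
    confusion_counts: np.ndarray  # (3, 3) ints, rows = true class
    final_predictions: np.ndarray | None = None
    final_labels: np.ndarray | None = None


@dataclass
class RunSummary:
    """Aggregate over folds: ACC, STD, and confusion in percent."""

    acc_mean: float
    acc_std: float
    fold_results: list[FoldResult]
    confusion_percent: np.ndarray  # (3, 3), rows sum to 100

    def as_dict(self) -> dict:
        return {
            "acc_mean": self.acc_mean,
            "acc_std": self.acc_std,
            "class_names": list(CLASS_NAMES),
            "folds": [
                {
                    "held_out_subject": str(f.held_out_subject),
                    "fold_accuracy": f.fold_accuracy,
                    "per_epoch_test_accuracy": [float(a) for a in f.per_epoch_test_accuracy],
                    "confusion_counts": f.confusion_counts.tolist(),
                }
                for f in self.fold_results
            ],
            "confusion_percent": self.confusion_percent.tolist(),
        }


def loso_folds(subject_ids) -> list[tuple[tuple[str, ...], str]]:
    """One fold per subject: (train subjects, held-out subject), sorted order."""
    subjects = sorted({str(s) for s in np.asarray(subject_ids).ravel()})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [
        (tuple(s for s in subjects if s != held_out), held_out) for held_out in subjects
    ]


def split_tensor(
    tensor: BandFeatureTensor, train_subjects, test_subject: str
) -> tuple[BandFeatureTensor, BandFeatureTensor]:
    """Slice a feature tensor into disjoint train/test subsets by subject."""
    subjects = tensor.subject_ids.astype(str)
    train_subjects = {str(s) for s in train_subjects}
    if str(test_subject) in train_subjects:
        raise ValueError(f"subject leakage: {test_subject!r} present in the training set")
    train_mask = np.isin(subjects, sorted(train_subjects))
    test_mask = subjects == str(test_subject)
    if not test_mask.any():
        raise ValueError(f"no trials for held-out subject {test_subject!r}")

    def _slice(mask):
        return tensor.copy_with(
            values=tensor.values[mask],
            subject_ids=tensor.subject_ids[mask],
            labels=tensor.labels[mask],
            trial_ids=None if tensor.trial_ids is None else tensor.trial_ids[mask],
            n_windows=None if tensor.n_windows is None else tensor.n_windows[mask],
        )

    return _slice(train_mask), _slice(test_mask)


def _confusion(labels: np.ndarray, predictions: np.ndarray, k: int = 3) -> np.ndarray:
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (labels, predictions), 1)
    return counts


def train_fold(
    train: BandFeatureTensor,
    test: BandFeatureTensor,
    model_config: ModelConfig,
    train_config: TrainConfig,
    layout: ElectrodeLayout,
) -> FoldResult:
    """Train one LOSO fold and score the held-out subject each epoch."""
    overlap = set(train.subject_ids.astype(str)) & set(test.subject_ids.astype(str))
    if overlap:
        raise ValueError(f"subject leakage: {sorted(overlap)} in both train and test")
    model = SgcSrmModel(model_config, layout)
    optimizer = Adam(model.parameters(), lr=train_config.lr0)
    rng = np.random.default_rng(train_config.seed)
    x_train, y_train = train.values, train.labels.astype(int)
    x_test, y_test = test.values, test.labels.astype(int)
    held_out = str(test.subject_ids[0])

    per_epoch_acc: list[float] = []
    predictions = np.zeros(0, dtype=int)
    for epoch in range(train_config.epochs):
        optimizer.lr = train_config.lr_at(epoch)
        order = rng.permutation(len(y_train))
        epoch_loss = []
        for start in range(0, len(order), train_config.batch_size):
            batch = order[start : start + train_config.batch_size]
            if len(batch) < 2:
                continue  # batch norm needs >= 2 samples in training mode
            optimizer.zero_grad()
            total, value = model.loss(x_train[batch], y_train[batch], training=True)
            total.backward()
            optimizer.step()
            epoch_loss.append(value)
        predictions = model.predict(x_test)
        acc = float((predictions == y_test).mean())
        per_epoch_acc.append(acc)
        if epoch_loss:
            logger.info(
                "fold=%s epoch=%d lr=%.5f ce=%.4f l1=%.1f acc=%.3f",
                held_out, epoch, optimizer.lr,
                float(np.mean([v.cross_entropy for v in epoch_loss])),
                float(np.mean([v.l1 for v in epoch_loss])),
                acc,
            )
    window = train_config.metric_window
    return FoldResult(
        held_out_subject=held_out,
        per_epoch_test_accuracy=per_epoch_acc,
        fold_accuracy=float(np.mean(per_epoch_acc[-window:])),
        confusion_counts=_confusion(y_test, predictions),
        final_predictions=predictions,
        final_labels=y_test,
    )


def summarize_run(folds: list[FoldResult]) -> RunSummary:
    """Mean/population-STD of fold accuracies and aggregate confusion (%)."""
    if not folds:
        raise ValueError("no folds to summarize")
    accs = np.array([f.fold_accuracy for f in folds])
    counts = np.sum([f.confusion_counts for f in folds], axis=0).astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    percent = 100.0 * counts / np.where(row_sums > 0, row_sums, 1.0)
    return RunSummary(
        acc_mean=float(accs.mean()),
        acc_std=float(accs.std()),
        fold_results=list(folds),
        confusion_percent=percent,
    )


def run_loso(
    tensor: BandFeatureTensor,
    model_config: ModelConfig,
    train_config: TrainConfig,
    layout: ElectrodeLayout,
) -> RunSummary:
    """Full leave-one-subject-out cross-validation on a normalized tensor."""
    folds = []
    for train_subjects, held_out in loso_folds(tensor.subject_ids):
        train, test = split_tensor(tensor, train_subjects, held_out)
        folds.append(train_fold(train, test, model_config, train_config, layout))
    return summarize_run(folds)


#: Recognized ablation switches and the config change each one makes.
ABLATION_SWITCHES: tuple[str, ...] = ("-global", "-SRM", "-global-SRM", "freeze_adjacency")


def _apply_switch(config: ModelConfig, switch: str) -> ModelConfig:
    if switch == "-global":
        return replace(config, use_global=False)
    if switch == "-SRM":
        return replace(config, use_srm=False)
    if switch == "-global-SRM":
        return replace(config, use_global=False, use_srm=False)
    if switch == "freeze_adjacency":
        return replace(config, freeze_adjacency=True)
    raise ValueError(f"unknown ablation switch {switch!r}; known: {ABLATION_SWITCHES}")


def ablate(
    tensor: BandFeatureTensor,
    base_config: ModelConfig,
    train_config: TrainConfig,
    layout: ElectrodeLayout,
    switches: tuple[str, ...] = ("-global", "-SRM", "-global-SRM"),
) -> dict[str, RunSummary]:
    """Run the base model and each ablation switch on identical data/seeds."""
    results = {"base": run_loso(tensor, base_config, train_config, layout)}
    for switch in switches:
        config = _apply_switch(base_config, switch)
        results[switch] = run_loso(tensor, config, train_config, layout)
    return results


def band_sweep(
    tensor: BandFeatureTensor,
    base_config: ModelConfig,
    train_config: TrainConfig,
    layout: ElectrodeLayout,
    multi_band_sets: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, RunSummary]:
    """Single-band, direct multi-band, and fused multi-band comparisons.

    Produces one summary per mode: each band alone (B = 1), each multi-band
    set fed to a single shared encoder ("direct:<set>"), and each set with
    per-band encoders plus learnable fusion ("fusion:<set>").
    """
    from .features import select_bands

    if multi_band_sets is None:
        names = tensor.band_names
        multi_band_sets = {"all": tuple(names)}
        four = tuple(b for b in names if b != "delta")
        if four != tuple(names) and len(four) >= 2:
            multi_band_sets["four"] = four
    results: dict[str, RunSummary] = {}
    for band in tensor.band_names:
        sub = select_bands(tensor, (band,))
        config = replace(base_config, bands=(band,), mode="fusion")
        results[f"single:{band}"] = run_loso(sub, config, train_config, layout)
    for set_name, bands in multi_band_sets.items():
        missing = set(bands) - set(tensor.band_names)
        if missing:
            raise KeyError(f"bands not in tensor: {sorted(missing)}")
        sub = select_bands(tensor, bands)
        for mode in ("direct", "fusion"):
            config = replace(base_config, bands=tuple(bands), mode=mode)
            results[f"{mode}:{set_name}"] = run_loso(sub, config, train_config, layout)
    return results
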