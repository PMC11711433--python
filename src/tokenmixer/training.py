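"""Training and evaluation under the study protocol.

Models train from scratch with Adam on minibatches of 32 for a configurable
number of epochs (the study default is 100), binary or categorical
cross-entropy depending on the task, and on-the-fly geometric augmentation
of the training partition only.  Multi-class experiments use stratified
threefold cross-validation on the train+validation pool, keeping the 20%
test partition untouched.  Timing is accounted as total wall-clock training
time and its per-epoch average.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .architectures import ModelHandle
from .breakhis_io import (AugmentationConfig, DatasetSplit, ImageRecord,
                          augment)
from .metrics import (ConfusionMatrix, MetricReport, binary_report, confusion,
                      multiclass_report, roc_auc)
from .nn import Tensor

__all__ = ["TrainConfig", "TimingReport", "EvalReport", "FoldResult",
           "train", "evaluate", "crossvalidate_3fold",
           "SUBTYPE_ORDER", "records_to_labels"]

# fixed subtype -> index mapping (benign block first)
SUBTYPE_ORDER = ("AD", "FI", "PH", "TU", "DU", "LO", "MU", "PA")


@dataclass
class TrainConfig:
    task: str = "binary"            # "binary" or "multi"
    batch_size: int = 32
    epochs: int = 100
    optimizer: str = "adam"
    learning_rate: float = 1e-3     # Adam default; the study names only Adam
    seed: int = 0

    @property
    def loss(self) -> str:
        return ("binary cross-entropy" if self.task == "binary"
                else "categorical cross-entropy")


@dataclass
class TimingReport:
    start_time: float
    end_time: float
    num_epochs: int

    @property
    def total_training_time_s(self) -> float:
        return self.end_time - self.start_time

    @property
    def avg_time_per_epoch_s(self) -> float:
        return self.total_training_time_s / self.num_epochs


@dataclass
class EvalReport:
    metrics: MetricReport
    confusion: ConfusionMatrix
    n: int
    fold: int | None = None

    def to_dict(self) -> dict:
        return {"n": self.n, "fold": self.fold,
                "values": self.metrics.values,
                "per_class": self.metrics.per_class,
                "confusion": self.confusion.table.tolist(),
                "flags": self.metrics.flags}


@dataclass
class FoldResult:
    fold: int
    handle: ModelHandle
    report: EvalReport
    history: dict[str, list[float]] = field(default_factory=dict)


def records_to_labels(records: Sequence[ImageRecord], task: str) -> np.ndarray:
    if task == "binary":
        return np.array([1 if r.label_binary == "malignant" else 0
                         for r in records], dtype=np.int64)
    if task == "multi":
        return np.array([SUBTYPE_ORDER.index(r.label_subtype)
                         for r in records], dtype=np.int64)
    raise ValueError(f"unknown task {task!r}")


def _load_images(records: Sequence[ImageRecord], size: int) -> np.ndarray:
    return np.stack([r.load_pixels(size) for r in records]).astype(np.float32)


def _n_outputs(handle: ModelHandle) -> int:
    return int(getattr(handle.config, "n_classes"))


def _check_head(handle: ModelHandle, task: str) -> None:
    n_out = _n_outputs(handle)
    if task == "binary" and n_out not in (1, 2):
        raise ValueError(f"binary task needs a 1- or 2-unit head, got {n_out}")
    if task == "multi" and n_out != len(SUBTYPE_ORDER):
        raise ValueError(f"multi task needs an {len(SUBTYPE_ORDER)}-unit head, "
                         f"got {n_out}")


def _loss_and_probs(handle: ModelHandle, x: Tensor, y: np.ndarray):
    logits = handle.model(x)
    n_out = logits.shape[-1]
    if n_out == 1:
        probs = logits.sigmoid()
        loss = nn.binary_cross_entropy(probs, y.astype(np.float32))
        p1 = probs.numpy()[:, 0]
    else:
        onehot = np.eye(n_out, dtype=np.float32)[y]
        loss = nn.softmax_cross_entropy(logits, onehot)
        z = logits.numpy()
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        p1 = p[:, 1] if n_out == 2 else p
    return loss, p1


def _pred_from_probs(p: np.ndarray) -> np.ndarray:
    if p.ndim == 1:
        return (p >= 0.5).astype(np.int64)
    return p.argmax(axis=-1)


def train(handle: ModelHandle, split: DatasetSplit, config: TrainConfig,
          aug: AugmentationConfig | None = None,
          ) -> tuple[dict[str, list[float]], TimingReport]:
    """Fit ``handle`` on ``split.train``, validating on ``split.validation``.

    Augmentation (defaulting to the study settings) is applied on the fly to
    training images only.  Returns the per-epoch history (train/val loss and
    accuracy) and the wall-clock :class:`TimingReport`.
    """
    _check_head(handle, config.task)
    aug = AugmentationConfig() if aug is None else aug
    size = int(getattr(handle.config, "image_size", 224))
    y_train = records_to_labels(split.train, config.task)
    x_train = _load_images(split.train, size)
    has_val = len(split.validation) > 0
    if has_val:
        y_val = records_to_labels(split.validation, config.task)
        x_val = _load_images(split.validation, size)

    input_norm = getattr(handle.model, "input_norm", None)
    if input_norm is not None and float(input_norm.count.data[0]) == 0:
        input_norm.adapt(x_train)

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(handle.model.parameters(), lr=config.learning_rate)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    t0 = time.time()
    for _ in range(config.epochs):
        handle.model.set_training(True)
        order = rng.permutation(len(x_train))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = np.stack([augment(x_train[i], aug, rng) for i in idx])
            loss, probs = _loss_and_probs(handle, Tensor(batch), y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            hits += int((_pred_from_probs(probs) == y_train[idx]).sum())
            seen += len(idx)
        history["loss"].append(sum(losses) / seen)
        history["accuracy"].append(hits / seen)
        if has_val:
            handle.model.set_training(False)
            vloss, vprobs = _loss_and_probs(handle, Tensor(x_val), y_val)
            history["val_loss"].append(float(vloss.data))
            history["val_accuracy"].append(
                float((_pred_from_probs(vprobs) == y_val).mean()))
    t1 = time.time()
    handle.model.set_training(False)
    return history, TimingReport(start_time=t0, end_time=t1,
                                 num_epochs=config.epochs)


def evaluate(handle: ModelHandle, records: Sequence[ImageRecord],
             task: str = "binary", batch_size: int = 32,
             fold: int | None = None) -> EvalReport:
    """Inference + the full metric suite (confusion matrix, rates, ROC)."""
    if not records:
        raise ValueError("cannot evaluate on an empty record list")
    _check_head(handle, task)
    size = int(getattr(handle.config, "image_size", 224))
    y = records_to_labels(records, task)
    handle.model.set_training(False)
    probs = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        probs.append(handle.predict_proba(_load_images(chunk, size)))
    p = np.concatenate(probs)
    if task == "binary":
        scores = p if p.ndim == 1 else p[:, 1]
        rep = binary_report(y, _pred_from_probs(scores), scores)
        cm = confusion(y, _pred_from_probs(scores), K=2)
    else:
        y_pred = p.argmax(axis=-1)
        cm = confusion(y, y_pred, K=len(SUBTYPE_ORDER))
        rep = multiclass_report(cm)
        # macro one-vs-rest ROC-AUC when every class is present
        if len(np.unique(y)) == cm.K:
            aucs = [roc_auc((y == k).astype(int), p[:, k])[1]
                    for k in range(cm.K)]
            rep.values["auc_macro_ovr"] = float(np.mean(aucs))
    return EvalReport(metrics=rep, confusion=cm, n=len(records), fold=fold)


def crossvalidate_3fold(records: Sequence[ImageRecord],
                        builder: Callable[[int], ModelHandle],
                        config: TrainConfig,
                        aug: AugmentationConfig | None = None,
                        ) -> tuple[list[FoldResult], dict[str, tuple[float, float]]]:
    """Stratified threefold cross-validation.

    ``builder(seed)`` must return a fresh model handle.  Each fold trains on
    two thirds and is evaluated on the held-out third; the summary maps each
    metric to its (mean, sd) over folds.
    """
    y = records_to_labels(records, config.task)
    counts = np.bincount(y)
    if (counts[counts > 0] < 3).any():
        raise ValueError("every class needs >= 3 records for 3-fold CV")
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=config.seed)
    folds: list[FoldResult] = []
    for k, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        handle = builder(config.seed + k)
        fold_split = DatasetSplit(
            train=[records[i] for i in tr],
            validation=[], test=[records[i] for i in va],
            seed=config.seed)
        history, _ = train(handle, fold_split, config, aug)
        report = evaluate(handle, fold_split.test, task=config.task, fold=k)
        folds.append(FoldResult(fold=k, handle=handle, report=report,
                                history=history))
    keys = folds[0].report.metrics.values.keys()
    summary = {}
    for key in keys:
        vals = [f.report.metrics.values.get(key) for f in folds]
        vals = [v for v in vals if v is not None]
        summary[key] = (float(np.mean(vals)), float(np.std(vals)))
    return folds, summary
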