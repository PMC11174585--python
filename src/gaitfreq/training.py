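"""Dataset splitting, SGD training loop, metrics, and the ablation runner.

Training is plain seeded mini-batch SGD with momentum on the label-smoothed
cross-entropy; model selection keeps the parameters of the epoch with the
best validation accuracy (earliest epoch on ties).  Runs are bit-reproducible
for a fixed seed on a single CPU thread.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import load_layout
from .pyramid import FPGCN, ModelConfig, TCNClassifier
from .synthetic import SkeletonSequence

__all__ = [
    "TrainConfig",
    "TrainResult",
    "ConfusionCounts",
    "AccuracyReport",
    "split_dataset",
    "stack_sequences",
    "normalize_sequences",
    "train_model",
    "confusion_matrix",
    "evaluate_accuracy",
    "accuracy_from_counts",
    "evaluate_model",
    "run_ablation",
]


@dataclass
class TrainConfig:
    """Optimization settings.

    The learning-rate default (1e-4) matches a long full-scale training
    schedule; the desk-scale benchmark configuration in
    :mod:`gaitfreq.benchmark` uses a larger rate suited to ~30 epochs.
    """

    learning_rate: float = 1e-4
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 16
    split_ratio: tuple[float, float, float] = (8.0, 1.0, 1.0)
    epsilon: float = 0.1  # label smoothing
    seed: int = 0
    normalize: bool = True

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if min(self.split_ratio) < 0 or sum(self.split_ratio) <= 0:
            raise ValueError("split ratios must be non-negative and sum-normalizable")


@dataclass
class TrainResult:
    model: object
    history: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float
    splits: tuple[list, list, list]  # train / val / test sequence lists
    test_accuracy: float | None = None


# -- splitting -------------------------------------------------------------


def split_dataset(data: list, ratio=(8, 1, 1), seed: int = 0, labels=None):
    """Stratified, deterministic three-way split.

    Within each class the items are shuffled with the seeded generator and
    dealt out so that the global split sizes track ``len(data) * ratio`` as
    closely as integer counts allow (largest-deficit assignment of the
    per-class remainders).  The three returned lists partition the input.
    """
    ratio = np.asarray(ratio, dtype=np.float64)
    if ratio.shape != (3,) or ratio.min() < 0 or ratio.sum() <= 0:
        raise ValueError("ratio must be three non-negative numbers")
    frac = ratio / ratio.sum()
    n = len(data)
    targets = n * frac
    if np.any(np.floor(targets + 1e-9) < 1):
        raise ValueError(f"ratio {tuple(ratio)} leaves a split empty for n={n}")
    if labels is None:
        labels = [item.label for item in data]
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assigned: list[list[int]] = [[], [], []]
    counts = np.zeros(3)
    leftovers: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        base = np.floor(len(idx) * frac).astype(int)
        pos = 0
        for s in range(3):
            assigned[s].extend(idx[pos : pos + base[s]].tolist())
            pos += base[s]
        counts += base
        leftovers.extend(int(j) for j in idx[pos:])
    for j in leftovers:  # one at a time to the most under-target split
        s = int(np.argmax(targets - counts))
        assigned[s].append(j)
        counts[s] += 1
    if any(len(a) == 0 for a in assigned):
        raise ValueError("too few items for a stratified three-way split")
    return tuple([data[i] for i in sorted(a)] for a in assigned)


# -- array plumbing --------------------------------------------------------


def stack_sequences(seqs: list[SkeletonSequence]):
    """Stack a homogeneous sequence list into (N, C, T, V) + labels."""
    x = np.stack([s.values for s in seqs], axis=0)
    y = np.asarray([s.label for s in seqs], dtype=np.intp)
    return x, y


def normalize_sequences(x: np.ndarray, layout="kinect25") -> np.ndarray:
    """Center each frame on the layout's pelvis joints and scale by torso length.

    Standard skeleton preprocessing: removes global translation per frame and
    subject scale per sequence.  Operates on (N, C, T, V) or (C, T, V).
    """
    if isinstance(layout, str):
        layout = load_layout(layout)
    single = x.ndim == 3
    x = x[None] if single else x
    center = x[:, :, :, list(layout.center_joints)].mean(axis=3, keepdims=True)
    out = x - center
    a, b = layout.scale_joints
    torso = np.linalg.norm(out[:, :, :, a] - out[:, :, :, b], axis=1)  # (N, T)
    scale = torso.mean(axis=1)  # (N,)
    scale = np.where(scale < 1e-9, 1.0, scale)
    out = out / scale[:, None, None, None]
    return out[0] if single else out


# -- metrics ---------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts per class, from a K-class confusion matrix."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_total: int
    matrix: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        sums = self.tp + self.fp + self.tn + self.fn
        if not np.all(sums == self.n_total):
            raise ValueError("per-class counts must sum to n_total")


def confusion_matrix(preds, labels, n_classes: int) -> ConfusionCounts:
    preds = np.asarray(preds, dtype=np.intp)
    labels = np.asarray(labels, dtype=np.intp)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must align")
    n = preds.size
    if n == 0:
        raise ValueError("need at least one prediction")
    if preds.min() < 0 or preds.max() >= n_classes or labels.max() >= n_classes:
        raise ValueError("class index out of range")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (labels, preds), 1)
    tp = np.diag(mat).astype(np.int64)
    fn = mat.sum(axis=1) - tp
    fp = mat.sum(axis=0) - tp
    tn = n - tp - fn - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_total=n, matrix=mat)


def accuracy_from_counts(tp, fp, tn, fn) -> float:
    """(TP + TN) / (TP + FP + TN + FN) for one one-vs-rest class."""
    total = tp + fp + tn + fn
    if total < 1:
        raise ValueError("empty confusion counts")
    return (tp + tn) / total


@dataclass
class AccuracyReport:
    """Micro (sample-weighted) and per-class one-vs-rest accuracies.

    ``macro`` is the unweighted mean of the per-class one-vs-rest values;
    the two can differ, so both are always reported explicitly.
    """

    micro: float
    per_class: np.ndarray
    macro: float


def evaluate_accuracy(counts: ConfusionCounts) -> AccuracyReport:
    if counts.n_total < 1:
        raise ValueError("n_total must be >= 1")
    per_class = (counts.tp + counts.tn) / counts.n_total
    micro = counts.tp.sum() / counts.n_total
    return AccuracyReport(micro=float(micro), per_class=per_class, macro=float(per_class.mean()))


# -- training --------------------------------------------------------------


def _batched_predict(model, x, batch_size=64):
    return np.concatenate(
        [model.predict(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    )


def _evaluate_split(model, x, y, epsilon, batch_size=64):
    """One forward pass per batch yields both loss and accuracy."""
    from . import autodiff as ad

    tot, hits = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        scores = model.forward(xb)
        tot += float(ad.label_smoothed_ce(scores, yb, epsilon).data) * len(xb)
        hits += int((np.argmax(scores.data, axis=1) == yb).sum())
    return tot / len(x), hits / len(x)


def train_model(
    model_config: ModelConfig,
    data: list[SkeletonSequence],
    train_config: TrainConfig,
    model_cls=None,
) -> TrainResult:
    """Split, train with seeded SGD + momentum, return best-validation model.

    `data` is a labelled sequence list; it is split 8:1:1 (stratified, by
    ``train_config.split_ratio``) and the test split is evaluated once with
    the selected parameters.
    """
    cfg = train_config
    train, val, test = split_dataset(data, cfg.split_ratio, cfg.seed)
    labels = {s.label for s in train}
    if len(labels) < 2:
        raise ValueError("training split must contain at least 2 classes")
    x_tr, y_tr = stack_sequences(train)
    x_va, y_va = stack_sequences(val)
    x_te, y_te = stack_sequences(test)
    if cfg.normalize:
        layout = model_config.layout
        x_tr = normalize_sequences(x_tr, layout)
        x_va = normalize_sequences(x_va, layout)
        x_te = normalize_sequences(x_te, layout)

    cls = model_cls if model_cls is not None else FPGCN
    model = cls(dataclasses.replace(model_config, init_seed=cfg.seed))
    x_tr = x_tr.astype(model.dtype)
    x_va = x_va.astype(model.dtype)
    x_te = x_te.astype(model.dtype)
    rng = np.random.default_rng(cfg.seed + 1)
    velocity = {k: np.zeros_like(p.data) for k, p in model.trainable().items()}

    rows = []
    best_state, best_acc, best_epoch = model.state_dict(), -1.0, -1
    n = len(x_tr)
    from . import autodiff as ad

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_hits = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            model.zero_grad()
            scores = model.forward(x_tr[sel])
            loss = ad.label_smoothed_ce(scores, y_tr[sel], cfg.epsilon)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            loss.backward()
            for k, p in model.trainable().items():
                g = p.grad if p.grad is not None else 0.0
                velocity[k] = cfg.momentum * velocity[k] + g
                p.data = p.data - cfg.learning_rate * velocity[k]
            epoch_loss += float(loss.data) * len(sel)
            epoch_hits += int((np.argmax(scores.data, axis=1) == y_tr[sel]).sum())
        # train accuracy is the running estimate over the epoch's batches
        train_acc = epoch_hits / n
        val_loss, val_acc = _evaluate_split(model, x_va, y_va, cfg.epsilon)
        rows.append(
            dict(
                epoch=epoch,
                train_loss=epoch_loss / n,
                train_accuracy=train_acc,
                val_loss=val_loss,
                val_accuracy=val_acc,
            )
        )
        if val_acc > best_acc:  # ties keep the earliest epoch
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    test_acc = float(np.mean(_batched_predict(model, x_te) == y_te))
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_accuracy=best_acc,
        splits=(train, val, test),
        test_accuracy=test_acc,
    )


def evaluate_model(model, seqs: list[SkeletonSequence], normalize=True) -> AccuracyReport:
    """Accuracy report of a trained model on a labelled sequence list."""
    x, y = stack_sequences(seqs)
    if normalize:
        x = normalize_sequences(x, model.config.layout)
    preds = _batched_predict(model, x)
    return evaluate_accuracy(confusion_matrix(preds, y, model.config.num_classes))


# -- ablation runner -------------------------------------------------------


def run_ablation(
    data: list[SkeletonSequence],
    base_config: ModelConfig,
    train_config: TrainConfig,
    seeds=(0, 1, 2),
) -> pd.DataFrame:
    """Train the three variants under identical seeds/splits; per-seed test
    accuracy rows plus a mean/sd summary are returned as a tidy table."""
    rows = []
    for seed in seeds:
        for variant in ("fgcn_only", "pgcn_only", "fpgcn"):
            mc = dataclasses.replace(base_config, ablation=variant)
            tc = dataclasses.replace(train_config, seed=int(seed))
            res = train_model(mc, data, tc)
            rows.append(dict(seed=int(seed), variant=variant,
                             test_accuracy=res.test_accuracy))
    return pd.DataFrame(rows)
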