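"""Training harness: SGD-family optimizers, step learning-rate schedule,
stratified k-fold cross-validation and the fully seeded training loop.

Defaults mirror the reference protocol: SGD with momentum 0.9 and weight
decay 5e-4 on a categorical cross-entropy loss over logits, base learning
rate 0.001 decayed by gamma = 0.5 every ``step_period`` epochs, batch size
64, 40 epochs, 10-fold cross-validation.  Augmentation is applied strictly
after splitting, so no augmented sibling of a test image can leak into its
training fold.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .data import DatasetManifest, balance_augment, resolve_image
from .metrics import MetricsReport, confusion_matrix, macro_report
from .model import ModelConfig, ShuffleNetLight, build_model
from ._tensor import Tensor, cross_entropy_logits

__all__ = [
    "OPTIMIZERS",
    "TrainConfig",
    "TrainHistory",
    "cross_validate",
    "load_checkpoint",
    "lr_at",
    "make_optimizer",
    "manifest_to_arrays",
    "save_checkpoint",
    "stratified_kfold",
    "train",
]

from .data import CLASSES


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "sgd"
    base_lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 64
    epochs: int = 40
    gamma: float = 0.5
    step_period: int = 10
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    epoch_seconds: list = field(default_factory=list)
    steps: int = 0
    best_epoch: int = -1
    best_val_acc: float = -1.0


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Step schedule: base_lr * gamma ** floor(epoch / step_period)."""
    return cfg.base_lr * cfg.gamma ** (int(epoch) // cfg.step_period)


# -- optimizers ---------------------------------------------------------------

class _Optimizer:
    def __init__(self, params, cfg: TrainConfig):
        self.params = list(params)
        self.cfg = cfg
        self.lr = cfg.base_lr
        self.state = [{} for _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, st in zip(self.params, self.state):
            if p.grad is None:
                continue
            g = p.grad + self.cfg.weight_decay * p.data
            self._update(p, g, st)

    def _update(self, p, g, st):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(_Optimizer):
    def _update(self, p, g, st):
        v = st.get("v")
        v = g if v is None else self.cfg.momentum * v + g
        st["v"] = v
        p.data -= self.lr * v


class Adam(_Optimizer):
    b1, b2, eps = 0.9, 0.999, 1e-8

    def _update(self, p, g, st):
        m = st.get("m", np.zeros_like(g))
        v = st.get("v", np.zeros_like(g))
        m = self.b1 * m + (1 - self.b1) * g
        v = self.b2 * v + (1 - self.b2) * g * g
        st["m"], st["v"] = m, v
        mh = m / (1 - self.b1**self.t)
        vh = v / (1 - self.b2**self.t)
        p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


class Nadam(Adam):
    def _update(self, p, g, st):
        m = st.get("m", np.zeros_like(g))
        v = st.get("v", np.zeros_like(g))
        m = self.b1 * m + (1 - self.b1) * g
        v = self.b2 * v + (1 - self.b2) * g * g
        st["m"], st["v"] = m, v
        mh = (self.b1 * m + (1 - self.b1) * g) / (1 - self.b1**self.t)
        vh = v / (1 - self.b2**self.t)
        p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


class RMSprop(_Optimizer):
    rho, eps = 0.9, 1e-8

    def _update(self, p, g, st):
        v = st.get("v", np.zeros_like(g))
        v = self.rho * v + (1 - self.rho) * g * g
        st["v"] = v
        p.data -= self.lr * g / (np.sqrt(v) + self.eps)


class Adamax(_Optimizer):
    b1, b2, eps = 0.9, 0.999, 1e-8

    def _update(self, p, g, st):
        m = st.get("m", np.zeros_like(g))
        u = st.get("u", np.zeros_like(g))
        m = self.b1 * m + (1 - self.b1) * g
        u = np.maximum(self.b2 * u, np.abs(g))
        st["m"], st["u"] = m, u
        p.data -= self.lr / (1 - self.b1**self.t) * m / (u + self.eps)


class Adadelta(_Optimizer):
    rho, eps = 0.95, 1e-6

    def _update(self, p, g, st):
        v = st.get("v", np.zeros_like(g))
        d = st.get("d", np.zeros_like(g))
        v = self.rho * v + (1 - self.rho) * g * g
        upd = np.sqrt(d + self.eps) / np.sqrt(v + self.eps) * g
        d = self.rho * d + (1 - self.rho) * upd * upd
        st["v"], st["d"] = v, d
        p.data -= self.lr * upd


OPTIMIZERS = {
    "sgd": SGD,
    "adam": Adam,
    "rmsprop": RMSprop,
    "adamax": Adamax,
    "adadelta": Adadelta,
    "nadam": Nadam,
}


def make_optimizer(model, cfg: TrainConfig) -> _Optimizer:
    name = cfg.optimizer.lower()
    if name not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}; choose from {sorted(OPTIMIZERS)}")
    return OPTIMIZERS[name](model.parameters(), cfg)


# -- data plumbing ------------------------------------------------------------

_LABEL_INDEX = {c: i for i, c in enumerate(CLASSES)}


def manifest_to_arrays(manifest: DatasetManifest, index=None):
    """Materialize active records as (N, 3, S, S) float32 images + int labels."""
    index = index if index is not None else manifest.index()
    recs = manifest.active_records()
    images = np.stack(
        [resolve_image(r, index).transpose(2, 0, 1) for r in recs]
    ).astype(np.float32)
    labels = np.array([_LABEL_INDEX[r.class_label] for r in recs], dtype=np.intp)
    return images, labels


def stratified_kfold(manifest: DatasetManifest, folds: int, seed: int):
    """Class-stratified partition into ``folds`` disjoint covering test sets.

    Returns a list of (train_ids, test_ids).  Each class's per-fold counts
    differ by at most one; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for rec in manifest.active_records():
        by_class.setdefault(rec.class_label, []).append(rec.id)
    fold_ids: list[list[str]] = [[] for _ in range(folds)]
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        if len(ids) < folds:
            raise ValueError(
                f"class {label} has {len(ids)} samples, fewer than {folds} folds"
            )
        order = rng.permutation(len(ids))
        for j, idx in enumerate(order):
            fold_ids[j % folds].append(ids[idx])
    all_ids = {r.id for r in manifest.active_records()}
    splits = []
    for j in range(folds):
        test = list(fold_ids[j])
        train = sorted(all_ids.difference(test))
        splits.append((train, sorted(test)))
    return splits


# -- training loop ------------------------------------------------------------

def _evaluate(model, images, labels, batch_size=64):
    model.eval()
    losses, correct = [], 0
    for lo in range(0, len(images), batch_size):
        xb = images[lo : lo + batch_size]
        yb = labels[lo : lo + batch_size]
        logits = model.forward(xb)
        losses.append(float(cross_entropy_logits(logits, yb).data) * len(yb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(images)), correct / len(images)


def train(model: ShuffleNetLight, train_data, val_data, cfg: TrainConfig):
    """Seeded training run; returns (model, TrainHistory).

    ``train_data`` / ``val_data`` are either :class:`DatasetManifest`
    instances or pre-materialized ``(images, labels)`` pairs.  The model's
    best-validation-accuracy weights are restored before returning.
    """
    xs, ys = (
        manifest_to_arrays(train_data)
        if isinstance(train_data, DatasetManifest)
        else train_data
    )
    xv, yv = (
        manifest_to_arrays(val_data)
        if isinstance(val_data, DatasetManifest)
        else val_data
    )
    if len(xs) == 0 or len(xv) == 0:
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(cfg.seed)
    opt = make_optimizer(model, cfg)
    history = TrainHistory()
    best_state = None
    for epoch in range(cfg.epochs):
        tic = time.perf_counter()
        opt.lr = lr_at(epoch, cfg)
        model.train()
        order = rng.permutation(len(xs))
        losses, correct = [], 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            logits = model.forward(Tensor(xs[idx]))
            loss = cross_entropy_logits(logits, ys[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {history.steps} (lr={opt.lr})"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            history.steps += 1
            losses.append(float(loss.data) * len(idx))
            correct += int((logits.data.argmax(axis=1) == ys[idx]).sum())
        val_loss, val_acc = _evaluate(model, xv, yv, cfg.batch_size)
        history.train_loss.append(float(np.sum(losses) / len(xs)))
        history.train_acc.append(correct / len(xs))
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.lr.append(opt.lr)
        history.epoch_seconds.append(time.perf_counter() - tic)
        if val_acc > history.best_val_acc:
            history.best_val_acc = val_acc
            history.best_epoch = epoch
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def cross_validate(
    manifest: DatasetManifest,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    augment_cfg=None,
    target_per_class: int | None = None,
):
    """k-fold protocol: one model per fold trained from scratch.

    Augmentation/balancing (when requested) is applied to each training fold
    after the split.  Returns (per-fold MetricsReports, aggregate) where the
    aggregate maps each macro metric to (mean, sd) over folds.
    """
    splits = stratified_kfold(manifest, train_cfg.folds, train_cfg.seed)
    reports: list[MetricsReport] = []
    for fold, (train_ids, test_ids) in enumerate(splits):
        train_man = manifest.subset(train_ids)
        if target_per_class is not None:
            train_man = balance_augment(train_man, target_per_class, augment_cfg)
        # augmented records resolve against the full training-fold index only
        test_man = manifest.subset(test_ids)
        model = build_model(model_cfg, seed=train_cfg.seed + fold)
        xt, yt = manifest_to_arrays(test_man)
        model, _ = train(model, train_man, (xt, yt), train_cfg)
        model.eval()
        preds = []
        for lo in range(0, len(xt), train_cfg.batch_size):
            preds.append(model.forward(xt[lo : lo + train_cfg.batch_size]).data.argmax(axis=1))
        cm = confusion_matrix(yt, np.concatenate(preds), model_cfg.n_classes)
        reports.append(macro_report(cm))
    aggregate = {
        m: (
            float(np.mean([r.macro[m] for r in reports])),
            float(np.std([r.macro[m] for r in reports])),
        )
        for m in reports[0].macro
    }
    return reports, aggregate


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: ShuffleNetLight, path) -> None:
    """npz weight archive plus a JSON sidecar recording the configuration."""
    state = model.state_dict()
    np.savez(path, **{k.replace(":", "__"): v for k, v in state.items()})
    with open(str(path) + ".json", "w") as fh:
        json.dump(model.cfg.to_dict(), fh, indent=2)


def load_checkpoint(path) -> ShuffleNetLight:
    with open(str(path) + ".json") as fh:
        cfg = ModelConfig.from_dict(json.load(fh))
    model = build_model(cfg)
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        state = {k.replace("__", ":"): data[k] for k in data.files}
    model.load_state_dict(state)
    return model
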