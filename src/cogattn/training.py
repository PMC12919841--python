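"""Training and evaluation protocol.

The default configuration mirrors a standard smear-classification recipe:
SGD with momentum 0.9, learning rate 0.001, L2 weight decay 0.005, batch
size 16, 30 epochs, cross-entropy loss, constant learning rate, inputs
resized bilinearly to the configured size and normalized per channel to
mean 0.5 / std 0.5.  Runs are deterministic under a seed: parameter
initialization, batch order and evaluation order are all fixed.

``run_experiment`` orchestrates the model-variant x split-mode grid on a
synthetic dataset and emits per-variant metric reports (plus per-fold
summaries in cross-validation mode).
"""

from __future__ import annotations

import io
import csv
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import transform as sktransform

from . import nn
from ._tensor import Tensor, cross_entropy, no_grad
from .attention import AttentionConfig
from .backbones import BackboneSpec, build_model
from .metrics import (ConfusionMatrix, FoldSummary, MetricReport,
                      binary_metrics, macro_metrics)
from .splits import SplitPlan, stratified_holdout, stratified_kfold

__all__ = ["TrainConfig", "TrainLog", "prepare_images", "train", "evaluate",
           "run_experiment", "ExperimentResult", "load_image_folder"]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp")


def load_image_folder(root, size=(224, 224)):
    """Load a class-per-subfolder image tree.

    Returns ``(images, labels, class_names)`` with images as a uint8 NHWC
    array resized bilinearly to ``size``; class order is alphabetical.
    """
    from pathlib import Path
    from PIL import Image

    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subfolders found under {root}")
    images, labels = [], []
    for label, cdir in enumerate(class_dirs):
        paths = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        if not paths:
            raise ValueError(f"class folder {cdir} contains no images")
        for p in paths:
            img = Image.open(p).convert("RGB").resize(size[::-1], Image.BILINEAR)
            images.append(np.asarray(img, dtype=np.uint8))
            labels.append(label)
    return (np.stack(images), np.asarray(labels, dtype=np.int64),
            [d.name for d in class_dirs])


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    epochs: int = 30
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.005
    input_size: tuple = (3, 224, 224)
    seed: int = 0
    select_best: bool = False   # restore the best-validation-accuracy epoch

    def __post_init__(self):
        if min(self.batch_size, self.learning_rate, self.input_size[1],
               self.input_size[2]) <= 0 or self.epochs < 0:
            raise ValueError("invalid training configuration")


@dataclass
class TrainLog:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
        for i in range(len(self)):
            w.writerow([i, self.train_loss[i], self.train_acc[i],
                        self.val_loss[i] if self.val_loss else "",
                        self.val_acc[i] if self.val_acc else ""])
        return buf.getvalue()


def prepare_images(images: np.ndarray, size: tuple) -> np.ndarray:
    """uint8 NHWC images -> float32 NCHW, resized, normalized to [-1, 1]."""
    _, h, w = size
    out = np.empty((len(images), 3, h, w), dtype=np.float32)
    for i, img in enumerate(images):
        x = img.astype(np.float32) / 255.0
        if img.shape[:2] != (h, w):
            x = sktransform.resize(x, (h, w), order=1, preserve_range=True,
                                   anti_aliasing=False).astype(np.float32)
        out[i] = np.moveaxis((x - 0.5) / 0.5, -1, 0)
    return out


def _coerce_data(data):
    if hasattr(data, "images") and hasattr(data, "labels"):
        return data.images, np.asarray(data.labels)
    images, labels = data
    return np.asarray(images), np.asarray(labels)


def _forward_batches(model, x: np.ndarray, batch_size: int) -> np.ndarray:
    """Eval-mode logits over a prepared array, batched."""
    was_training = model.training
    model.eval()
    outs = []
    try:
        with no_grad():
            for s in range(0, len(x), batch_size):
                outs.append(model(Tensor(x[s:s + batch_size])).data)
    finally:
        model.train(was_training)
    return np.concatenate(outs) if outs else np.empty((0, model.num_classes))


def train(model, data, splits: SplitPlan, config: TrainConfig,
          fold: int | None = None):
    """Train ``model`` in place; returns ``(model, TrainLog)``.

    ``splits`` selects the samples: a holdout plan uses its train and val
    partitions; a k-fold plan with ``fold`` given uses that fold's train
    indices (no validation curve).
    """
    images, labels = _coerce_data(data)
    if splits.mode == "holdout":
        train_idx = splits.indices("train")
        val_idx = splits.indices("val")
    else:
        if fold is None:
            raise ValueError("training on a k-fold plan requires fold=...")
        train_idx, _ = splits.fold_indices(fold)
        val_idx = np.empty(0, dtype=int)
    if len(train_idx) == 0:
        raise ValueError("empty training partition")

    x_all = prepare_images(images, config.input_size)
    y_all = labels.astype(np.int64)
    xt, yt = x_all[train_idx], y_all[train_idx]
    xv, yv = x_all[val_idx], y_all[val_idx]

    opt = nn.SGD(model.parameters(), lr=config.learning_rate,
                 momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    log = TrainLog()
    best = (-1.0, None)

    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(xt))
        losses, correct = [], 0
        for s in range(0, len(order), config.batch_size):
            sel = order[s:s + config.batch_size]
            xb, yb = xt[sel], yt[sel]
            opt.zero_grad()
            logits = model(Tensor(xb, requires_grad=True))
            loss = cross_entropy(logits, yb)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {s // config.batch_size} (loss={value})")
            loss.backward()
            opt.step()
            losses.append(value)
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        log.train_loss.append(float(np.mean(losses)))
        log.train_acc.append(100.0 * correct / len(xt))

        if len(xv):
            logits = _forward_batches(model, xv, config.batch_size)
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            vl = float(-np.log(np.maximum(
                p[np.arange(len(yv)), yv], 1e-12)).mean())
            va = 100.0 * float((logits.argmax(axis=1) == yv).mean())
            log.val_loss.append(vl)
            log.val_acc.append(va)
            if config.select_best and va > best[0]:
                best = (va, model.state_dict())

    if config.select_best and best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, log


def evaluate(model, data, indices=None, config: TrainConfig | None = None):
    """Deterministic evaluation; returns ``(ConfusionMatrix, MetricReport)``."""
    config = config or TrainConfig()
    images, labels = _coerce_data(data)
    if indices is not None:
        images, labels = images[indices], labels[indices]
    if len(labels) == 0:
        raise ValueError("evaluation partition is empty")
    x = prepare_images(images, config.input_size)
    logits = _forward_batches(model, x, config.batch_size)
    preds = logits.argmax(axis=1)
    cm = ConfusionMatrix.from_predictions(labels, preds, n_classes=model.num_classes)
    report = binary_metrics(cm) if model.num_classes == 2 else macro_metrics(cm)
    return cm, report


@dataclass
class ExperimentResult:
    """Per-variant metric reports for one experiment manifest."""

    reports: dict          # variant name -> MetricReport
    fold_summaries: dict   # variant name -> FoldSummary (kfold mode only)
    logs: dict             # variant name -> TrainLog or list of TrainLog

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["variant", "accuracy", "precision", "sensitivity",
                    "specificity", "f1"])
        for name, r in self.reports.items():
            rr = r.rounded()
            w.writerow([name, rr.accuracy, rr.precision, rr.sensitivity,
                        rr.specificity, rr.f1])
        return buf.getvalue()


def run_experiment(manifest: dict) -> ExperimentResult:
    """Run a {backbone} x {attention kinds} grid on a synthetic dataset.

    Manifest keys: ``dataset`` (a SyntheticDataset or SyntheticDatasetSpec),
    ``backbone`` (family, default "mini"), ``attention`` (list from
    {"none","pcab","scab"}), ``split`` ("holdout" or "kfold"), ``k``,
    ``train`` (TrainConfig), ``attention_config`` (AttentionConfig),
    ``seed``.
    """
    from .synthetic import SyntheticDatasetSpec, generate_dataset

    seed = int(manifest.get("seed", 0))
    dataset = manifest["dataset"]
    if isinstance(dataset, SyntheticDatasetSpec):
        dataset = generate_dataset(dataset)
    labels = np.asarray(dataset.labels)
    n_classes = int(labels.max()) + 1
    family = manifest.get("backbone", "mini")
    kinds = manifest.get("attention", ["none"])
    split_mode = manifest.get("split", "holdout")
    cfg = manifest.get("train", TrainConfig())
    cfg = replace(cfg, seed=seed)
    att_cfg = manifest.get("attention_config", AttentionConfig())
    spec = BackboneSpec(family=family, num_classes=n_classes)

    reports, fold_summaries, logs = {}, {}, {}
    for kind in kinds:
        name = family if kind == "none" else f"{family}+{kind}"
        if split_mode == "holdout":
            plan = stratified_holdout(labels, seed=seed)
            model, _ = build_model(spec, kind, att_cfg, seed=seed)
            model, log = train(model, dataset, plan, cfg)
            _, report = evaluate(model, dataset, plan.indices("test"), cfg)
            reports[name] = report
            logs[name] = log
        elif split_mode == "kfold":
            k = int(manifest.get("k", 5))
            plan = stratified_kfold(labels, k=k, seed=seed)
            fold_reports, fold_logs = [], []
            for fold in range(k):
                model, _ = build_model(spec, kind, att_cfg, seed=seed + fold)
                model, log = train(model, dataset, plan, cfg, fold=fold)
                _, test_idx = plan.fold_indices(fold)
                _, report = evaluate(model, dataset, test_idx, cfg)
                fold_reports.append(report)
                fold_logs.append(log)
            summary = FoldSummary(per_fold=fold_reports)
            fold_summaries[name] = summary
            reports[name] = summary.mean_report
            logs[name] = fold_logs
        else:
            raise ValueError(f"unknown split mode {split_mode!r}")
    return ExperimentResult(reports=reports, fold_summaries=fold_summaries, logs=logs)
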