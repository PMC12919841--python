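"""Stratified data splitting: 80/10/10 holdout and K-fold cross-validation.

The holdout rule is per class: ``floor(r_train * n_c)`` samples to train,
``floor(r_val * n_c)`` to validation, and the remainder to test, after a
seeded within-class shuffle.  The K-fold rule shuffles each class and deals
it into K contiguous chunks whose sizes differ by at most one, so every fold
preserves the class distribution up to one sample and every sample is tested
exactly once across the K train/test iterations.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplitPlan", "stratified_holdout", "stratified_kfold"]

PARTITIONS = ("train", "val", "test")


@dataclass
class SplitPlan:
    """Assignment of sample indices to partitions or folds."""

    mode: str                       # "holdout" or "kfold"
    assignment: np.ndarray          # partition index (0/1/2) or fold id
    labels: np.ndarray
    k: int = 0
    ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def indices(self, partition) -> np.ndarray:
        """Indices of one holdout partition ('train'/'val'/'test')."""
        if self.mode != "holdout":
            raise ValueError("indices(partition) applies to holdout plans")
        return np.flatnonzero(self.assignment == PARTITIONS.index(partition))

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one cross-validation fold."""
        if self.mode != "kfold":
            raise ValueError("fold_indices applies to k-fold plans")
        if not (0 <= fold < self.k):
            raise ValueError(f"fold must lie in [0, {self.k})")
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test

    def iter_folds(self):
        for k in range(self.k):
            yield self.fold_indices(k)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        if self.mode == "holdout":
            writer.writerow(["index", "label", "partition"])
            for i, (lab, a) in enumerate(zip(self.labels, self.assignment)):
                writer.writerow([i, int(lab), PARTITIONS[a]])
        else:
            writer.writerow(["index", "label", "fold"])
            for i, (lab, a) in enumerate(zip(self.labels, self.assignment)):
                writer.writerow([i, int(lab), int(a)])
        return buf.getvalue()


def stratified_holdout(labels, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> SplitPlan:
    """Per-class floor-rule train/val/test split (default 80/10/10)."""
    labels = np.asarray(labels, dtype=int)
    if len(ratios) != 3 or not np.isclose(sum(ratios), 1.0) or min(ratios) <= 0:
        raise ValueError("ratios must be three positive fractions summing to 1")
    assignment = np.empty(len(labels), dtype=np.int64)
    rng = np.random.default_rng(seed)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 3:
            raise ValueError(f"class {c} has {len(idx)} samples; "
                             "at least 3 are needed to populate train/val/test")
        rng.shuffle(idx)
        n_train = int(np.floor(ratios[0] * len(idx)))
        n_val = int(np.floor(ratios[1] * len(idx)))
        n_train = max(n_train, 1)
        n_val = max(n_val, 1)
        if n_train + n_val >= len(idx):   # guarantee a nonempty test partition
            n_train = len(idx) - 2
            n_val = 1
        assignment[idx[:n_train]] = 0
        assignment[idx[n_train:n_train + n_val]] = 1
        assignment[idx[n_train + n_val:]] = 2
    return SplitPlan(mode="holdout", assignment=assignment, labels=labels,
                     ratios=tuple(ratios), seed=seed)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified K-fold assignment; every class needs at least K samples."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    assignment = np.empty(len(labels), dtype=np.int64)
    rng = np.random.default_rng(seed)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(f"class {c} has {len(idx)} samples, fewer than k={k}")
        rng.shuffle(idx)
        # contiguous chunks whose sizes differ by at most one
        sizes = np.full(k, len(idx) // k)
        sizes[: len(idx) % k] += 1
        start = 0
        for fold, size in enumerate(sizes):
            assignment[idx[start:start + size]] = fold
            start += size
    return SplitPlan(mode="kfold", assignment=assignment, labels=labels,
                     k=k, seed=seed)
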