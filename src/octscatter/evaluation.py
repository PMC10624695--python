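"""Hold-out / k-fold evaluation: confusion matrices, accuracy, macro OvR AUC.

Splits are stratified by class and deterministic for a given seed.  The
multiclass AUC is the unweighted (macro) mean over classes of the one-vs-rest
ranking AUC computed from each class's score column (negated projection
residuals), with midrank tie handling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["EvaluationReport", "split_holdout", "kfold", "evaluate"]


@dataclass
class EvaluationReport:
    """Metrics of one evaluation: confusion, accuracy, per-class PRF, AUC."""

    class_order: list[str]
    confusion: np.ndarray  # (K, K), rows = true, cols = predicted
    accuracy: float
    per_class: dict[str, dict[str, float]]
    auc_macro: float
    folds: Optional[list["EvaluationReport"]] = None
    split_record: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "class_order": self.class_order,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "auc_macro": self.auc_macro,
            "split_record": _jsonable(self.split_record),
            "config": _jsonable(self.config),
        }
        if self.folds is not None:
            d["folds"] = [f.to_dict() for f in self.folds]
        return d

    def save(self, outdir) -> None:
        """Write report.json plus a CSV confusion matrix with class order."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        pd.DataFrame(
            self.confusion, index=self.class_order, columns=self.class_order
        ).to_csv(outdir / "confusion.csv")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def split_holdout(
    labels: Sequence, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split.

    Per class the train count is ``round(train_fraction * n_k)`` (half-up),
    clipped so both sides keep at least one sample.  Deterministic for a
    given seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for lab in sorted(np.unique(y).tolist()):
        idx = np.flatnonzero(y == lab)
        if idx.size < 2:
            raise ValueError(
                f"class {lab!r} has {idx.size} sample(s); need at least 2 to split"
            )
        n_train = int(np.floor(train_fraction * idx.size + 0.5))
        n_train = int(np.clip(n_train, 1, idx.size - 1))
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def kfold(labels: Sequence, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions; each sample is tested exactly once.

    Falls back to a plain (non-stratified) shuffled k-fold with a warning if
    some class has fewer than k samples.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > y.size:
        raise ValueError(f"k={k} exceeds the number of samples {y.size}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"smallest class has {counts.min()} < k={k} samples; "
            "using non-stratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros_like(y, dtype=float), y)]


def evaluate(
    true_labels: Sequence,
    predicted_labels: Sequence,
    scores: Optional[np.ndarray] = None,
    class_order: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Confusion matrix, accuracy, per-class precision/recall/F1, macro AUC.

    ``scores`` is an (n, K) matrix aligned to ``class_order`` (higher = more
    class-like; negated residuals for the scattering classifier).  Classes
    with no positive or no negative example are excluded from the AUC macro
    average.
    """
    y_true = np.asarray([str(v) for v in true_labels])
    y_pred = np.asarray([str(v) for v in predicted_labels])
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label lengths differ")
    if class_order is None:
        class_order = sorted(np.unique(y_true).tolist())
    class_order = [str(c) for c in class_order]
    unknown = set(y_pred) - set(class_order)
    if unknown:
        raise ValueError(f"predictions contain unknown labels: {sorted(unknown)}")

    conf = confusion_matrix(y_true, y_pred, labels=class_order)
    accuracy = float(np.trace(conf) / conf.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes yield 0/0 -> 0
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=class_order, zero_division=0
        )
    per_class = {
        c: {
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
            "support": int(s),
        }
        for c, p, r, f, s in zip(class_order, prec, rec, f1, support)
    }

    auc_macro = float("nan")
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (y_true.size, len(class_order)):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"(n={y_true.size}, K={len(class_order)})"
            )
        aucs = []
        for k, c in enumerate(class_order):
            pos = y_true == c
            if 0 < pos.sum() < y_true.size:
                aucs.append(roc_auc_score(pos, scores[:, k]))
        if aucs:
            auc_macro = float(np.mean(aucs))

    return EvaluationReport(
        class_order=list(class_order),
        confusion=conf,
        accuracy=accuracy,
        per_class=per_class,
        auc_macro=auc_macro,
    )
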