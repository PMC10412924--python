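"""Metrics and the leave-one-subject-out (LOSO) evaluation protocol.

Micro-expression recognition is reported with subject-exclusive cross
validation: each fold holds out every sample of one subject, so scores
measure generalization to unseen identities.  Headline numbers pool the
per-fold test predictions into a single confusion table (the MEGC-style
convention); per-fold reports are emitted alongside.

Per-class scores follow the usual one-vs-rest definitions

    Precision = TP/(TP+FP),  Recall = TP/(TP+FN),
    F1 = 2*Precision*Recall/(Precision+Recall)

with the 0/0 convention that a vanishing denominator scores 0.  The
unweighted (macro) aggregates are UF1 = mean of per-class F1 and
UAR = mean of per-class recall, both insensitive to class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfusionTable",
    "MetricsReport",
    "FoldSpec",
    "confusion",
    "class_metrics",
    "aggregate",
    "loso_folds",
    "map_to_3class",
    "evaluate_loso",
]


@dataclass
class ConfusionTable:
    """C x C count matrix, entry (true, predicted), with an ordered class list."""

    classes: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp_fp_fn_tn(self, label: str) -> tuple[int, int, int, int]:
        i = self._index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def _index(self, label: str) -> int:
        if label not in self.classes:
            raise ValueError(f"class {label!r} not in table classes {self.classes}")
        return self.classes.index(label)


@dataclass
class MetricsReport:
    fold_id: str
    classes: list[str]
    accuracy: float
    per_class: dict[str, dict[str, float]]  # label -> {precision, recall, f1}
    uf1: float
    uar: float
    weighted_f1: float
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "classes": self.classes,
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "uf1": self.uf1,
            "uar": self.uar,
            "weighted_f1": self.weighted_f1,
            "n_samples": self.n_samples,
        }


@dataclass
class FoldSpec:
    """One (held-out subject, train ids, test ids) triple per subject."""

    folds: list[tuple[str, list[str], list[str]]]


def confusion(y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]) -> ConfusionTable:
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionTable(classes=classes, counts=counts)


def class_metrics(table: ConfusionTable, label: str) -> tuple[float, float, float]:
    """(precision, recall, F1) for one class; 0/0 cases score 0."""
    tp, fp, fn, _ = table.tp_fp_fn_tn(label)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def aggregate(table: ConfusionTable, fold_id: str = "pooled") -> MetricsReport:
    """Accuracy, per-class scores and the unweighted UF1/UAR means."""
    if table.total == 0:
        raise ValueError("cannot aggregate an empty confusion table")
    per_class = {}
    f1s, recalls, supports = [], [], []
    for c in table.classes:
        precision, recall, f1 = class_metrics(table, c)
        per_class[c] = {"precision": precision, "recall": recall, "f1": f1}
        f1s.append(f1)
        recalls.append(recall)
        supports.append(table.counts[table._index(c), :].sum())
    supports = np.asarray(supports, dtype=float)
    weighted_f1 = float(np.sum(np.asarray(f1s) * supports) / supports.sum())
    return MetricsReport(
        fold_id=fold_id,
        classes=list(table.classes),
        accuracy=float(np.trace(table.counts) / table.total),
        per_class=per_class,
        uf1=float(np.mean(f1s)),
        uar=float(np.mean(recalls)),
        weighted_f1=weighted_f1,
        n_samples=table.total,
    )


def loso_folds(manifest: pd.DataFrame) -> FoldSpec:
    """One fold per distinct subject, ordered by sorted subject id."""
    subjects = sorted(manifest["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError(f"LOSO needs >= 2 subjects, got {len(subjects)}")
    folds = []
    for subj in subjects:
        held = manifest["subject_id"] == subj
        folds.append(
            (subj, manifest.loc[~held, "sample_id"].tolist(), manifest.loc[held, "sample_id"].tolist())
        )
    return FoldSpec(folds=folds)


_LABEL_MAP: dict | None = None


def _label_map() -> dict:
    global _LABEL_MAP
    if _LABEL_MAP is None:
        path = Path(__file__).parent / "data" / "label_map.yaml"
        _LABEL_MAP = yaml.safe_load(path.read_text())
    return _LABEL_MAP


def map_to_3class(label: str, source_dataset: str) -> str:
    """Project a dataset-native emotion label onto negative/positive/surprise.

    Happiness maps to positive; repression, sadness, contempt, disgust,
    anger and fear map to negative; surprise passes through, as do labels
    already in the 3-class scheme.  Unmappable labels (e.g. ``others``)
    raise; the caller is expected to filter them out explicitly.
    """
    vocab = _label_map()
    key = source_dataset.lower()
    if key not in vocab:
        raise ValueError(f"unknown source dataset {source_dataset!r}; known: {sorted(vocab)}")
    table = vocab[key]
    norm = label.lower()
    if norm not in table:
        raise ValueError(f"label {label!r} is not mappable for dataset {source_dataset!r}; filter it out")
    return table[norm]


def evaluate_loso(
    trainer: Callable,
    manifest: pd.DataFrame,
    classes: Sequence[str],
    seed: int = 0,
) -> tuple[list[MetricsReport], MetricsReport, list[str]]:
    """Run LOSO cross-validation with a user-supplied training procedure.

    ``trainer(train_rows, test_rows, seed)`` must return one predicted label
    per test row.  Per-fold seeds are derived deterministically from
    ``seed``.  Returns (per-fold reports, pooled report over all predictions,
    list of failed fold ids).  A failing fold is recorded and skipped.
    """
    spec = loso_folds(manifest)
    by_id = manifest.set_index("sample_id", drop=False)
    fold_reports: list[MetricsReport] = []
    failures: list[str] = []
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    for f, (subj, train_ids, test_ids) in enumerate(spec.folds):
        train_rows = by_id.loc[train_ids]
        test_rows = by_id.loc[test_ids]
        fold_seed = (seed * 1009 + f) % (2**31)
        try:
            preds = list(trainer(train_rows, test_rows, fold_seed))
        except Exception:
            failures.append(subj)
            continue
        if len(preds) != len(test_ids):
            failures.append(subj)
            continue
        truth = test_rows["label"].tolist()
        fold_reports.append(aggregate(confusion(truth, preds, classes), fold_id=subj))
        pooled_true.extend(truth)
        pooled_pred.extend(preds)
    if not pooled_true:
        raise RuntimeError("every LOSO fold failed; no predictions to aggregate")
    pooled = aggregate(confusion(pooled_true, pooled_pred, classes), fold_id="pooled")
    return fold_reports, pooled, failures
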