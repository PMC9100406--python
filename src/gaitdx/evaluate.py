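"""Evaluation: confusion matrix, macro-averaged accuracy/precision/sensitivity/F1,
one-vs-rest ROC/AUC, and the channel-combination experiment runner.

Per class (one-vs-rest): sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
F1 = 2TP/(2TP+FP+FN); the macro value is the unweighted class mean; accuracy is
trace/total. Metrics are reported as percentages (AUC on [0, 1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError


@dataclass
class ConfusionMatrix:
    """Class-by-class counts; rows are true labels, columns predicted."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ConfigurationError(f"counts shape {self.counts.shape} != ({c}, {c})")
        if (self.counts < 0).any():
            raise ConfigurationError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for one class against the rest."""
        tp = int(self.counts[class_index, class_index])
        fn = int(self.counts[class_index].sum() - tp)
        fp = int(self.counts[:, class_index].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


def confusion_matrix(true_labels, predicted_labels, classes) -> ConfusionMatrix:
    """Tally counts[i][j] = #{true = classes[i], predicted = classes[j]}."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise ParameterError("empty label sequences")
    if t.shape != p.shape:
        raise ParameterError(f"length mismatch: {t.shape} vs {p.shape}")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    for label in np.concatenate([t, p]):
        if label not in index:
            raise ParameterError(f"unknown label {label!r}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(classes, counts)


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, precision and F1 (percent) of one binary table."""
    total = tp + tn + fp + fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    acc = (tp + tn) / total if total else 0.0
    return {
        "accuracy": 100.0 * acc,
        "sensitivity": 100.0 * sens,
        "precision": 100.0 * prec,
        "f1": 100.0 * f1,
    }


def macro_metrics(cm: ConfusionMatrix) -> dict:
    """Macro-averaged one-vs-rest metrics plus overall accuracy, in percent."""
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    per_class: dict = {}
    for i, cls in enumerate(cm.classes):
        tp, tn, fp, fn = cm.one_vs_rest(i)
        if tp + fn == 0:
            warnings.warn(f"class {cls!r} absent from the test set; sensitivity set to 0", stacklevel=2)
        per_class[cls] = binary_metrics(tp, tn, fp, fn)
    macro = {
        m: float(np.mean([per_class[c][m] for c in cm.classes]))
        for m in ("sensitivity", "precision", "f1")
    }
    macro["accuracy"] = 100.0 * float(np.trace(cm.counts)) / cm.total
    macro["per_class"] = per_class
    return macro


def _auc_rank(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC (equals the trapezoidal ROC area with tie handling)."""
    scores = np.concatenate([pos_scores, neg_scores])
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    # average ranks over ties
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc_macro(true_labels, class_scores: np.ndarray, classes) -> dict:
    """One-vs-rest AUC per class plus the unweighted macro mean.

    ``class_scores`` rows must sum to 1 (one column per class in ``classes``).
    Degenerate (constant) scores yield AUC 0.5 with a warning.
    """
    t = np.asarray(true_labels)
    scores = np.asarray(class_scores, dtype=float)
    classes = tuple(classes)
    if scores.shape != (len(t), len(classes)):
        raise ParameterError(f"scores shape {scores.shape} != ({len(t)}, {len(classes)})")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ParameterError("class-score rows must sum to 1")
    out: dict = {}
    aucs = []
    for i, cls in enumerate(classes):
        pos = scores[t == cls, i]
        neg = scores[t != cls, i]
        if pos.size == 0 or neg.size == 0:
            out[cls] = 0.5
            aucs.append(0.5)
            continue
        if np.ptp(scores[:, i]) == 0.0:
            warnings.warn(f"degenerate constant scores for class {cls!r}; AUC = 0.5", stacklevel=2)
            out[cls] = 0.5
            aucs.append(0.5)
            continue
        a = _auc_rank(pos, neg)
        out[cls] = a
        aucs.append(a)
    out["macro"] = float(np.mean(aucs))
    return out


@dataclass
class EvalReport:
    """Pooled evaluation of one (channel-combo, ranker, top-k) configuration."""

    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    auc: float
    confusion: ConfusionMatrix
    per_class: dict
    auc_per_class: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 2),
            "precision": round(self.precision, 2),
            "sensitivity": round(self.sensitivity, 2),
            "f1": round(self.f1, 2),
            "auc": round(self.auc, 4),
            "confusion": {
                "classes": [str(c) for c in self.confusion.classes],
                "counts": self.confusion.counts.tolist(),
            },
            "provenance": dict(self.provenance),
        }


def build_report(cm: ConfusionMatrix, y_true, scores, classes) -> EvalReport:
    metrics = macro_metrics(cm)
    auc = roc_auc_macro(y_true, scores, classes)
    return EvalReport(
        accuracy=metrics["accuracy"],
        precision=metrics["precision"],
        sensitivity=metrics["sensitivity"],
        f1=metrics["f1"],
        auc=auc["macro"],
        confusion=cm,
        per_class=metrics["per_class"],
        auc_per_class={k: v for k, v in auc.items() if k != "macro"},
        provenance={},
    )


def channel_combos(channels: tuple[str, ...]) -> list[tuple[str, ...]]:
    """The 7 combos per modality: 3 singles, 3 pairs, 1 triple."""
    combos: list[tuple[str, ...]] = [(c,) for c in channels]
    combos += list(combinations(channels, 2))
    combos.append(tuple(channels))
    return combos


def channel_experiment(
    tables: dict[str, pd.DataFrame],
    combos: list[tuple[str, ...]],
    rankers: tuple[str, ...],
    labels,
    subject_ids,
    knn_config=None,
    n_folds: int = 5,
    seed: int = 0,
    max_k: int | None = None,
    prune_first: bool = True,
) -> pd.DataFrame:
    """Run prune -> rank -> incremental search -> KNN for every (combo, ranker).

    Returns one row per configuration with the best top-k and its pooled metrics,
    mirroring the per-channel evaluation tables of the study layout.
    """
    from . import classify, selection  # deferred to avoid a circular import
    from .pipeline import combine_channels, prune_and_rank

    for combo in combos:
        for ch in combo:
            if ch not in tables:
                raise ParameterError(f"missing feature table for channel {ch!r}")
    cfg = knn_config or classify.KnnConfig()
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    subjects = dict(zip(subject_ids.tolist(), labels.tolist()))
    folds = classify.subject_wise_folds(subjects, n_folds, seed)
    record_folds = folds.record_folds(subject_ids)

    rows = []
    for combo in combos:
        table = combine_channels(tables, combo)
        for method in rankers:
            pruned, ranked = prune_and_rank(table, labels, method, prune_first=prune_first)
            result = classify.incremental_feature_search(
                ranked, pruned, labels, record_folds, cfg, seed, subject_ids, max_k=max_k
            )
            r = result.best_report
            rows.append(
                {
                    "combo": "-".join(combo),
                    "ranker": method,
                    "top_k": result.best_k,
                    "accuracy": round(r.accuracy, 2),
                    "precision": round(r.precision, 2),
                    "sensitivity": round(r.sensitivity, 2),
                    "f1": round(r.f1, 2),
                    "auc": round(r.auc, 4),
                }
            )
    return pd.DataFrame(rows)
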