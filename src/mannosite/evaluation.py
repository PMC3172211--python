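"""Cross-validation driver and threshold-dependent performance measures.

Metrics follow the usual residue-prediction conventions: sensitivity
(percent of interacting residues recovered), specificity (percent of
non-interacting residues recovered), accuracy, and the Matthews correlation
coefficient

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)),

defined as 0 when any factor of the denominator vanishes.  Confusion counts
may be fractional so that metrics can also be reconstructed from printed
sensitivity/specificity percentages without rounding artifacts.  Model
ranking additionally uses the threshold-independent area under the ROC
curve, computed by the trapezoidal rule over all distinct score cutoffs
(equivalently the Mann-Whitney U statistic divided by n_pos * n_neg).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datasets import PatternDataset
from .encoders import Encoding, PSSMMatrix, encode_patterns
from .model import SvmConfig, train_on_vectors

DEFAULT_THRESHOLDS = tuple(round(t, 1) for t in np.arange(-1.0, 1.0 + 1e-9, 0.1))


class UndefinedMetricWarning(UserWarning):
    """A rate is undefined because one class is absent."""


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fp/tn/fn; reals permitted so rate-derived counts need not round."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> float:
        return self.tp + self.fn

    @property
    def negatives(self) -> float:
        return self.tn + self.fp


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """Return (Sen%, Spe%, Acc%, MCC) from a confusion table.

    Sen or Spe is NaN (with a warning) when the corresponding class is
    empty; MCC is 0 whenever a denominator factor vanishes.
    """
    sen = spe = float("nan")
    if c.positives > 0:
        sen = 100.0 * c.tp / c.positives
    else:
        warnings.warn("no positives: sensitivity undefined", UndefinedMetricWarning)
    if c.negatives > 0:
        spe = 100.0 * c.tn / c.negatives
    else:
        warnings.warn("no negatives: specificity undefined", UndefinedMetricWarning)
    total = c.positives + c.negatives
    acc = 100.0 * (c.tp + c.tn) / total if total > 0 else float("nan")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return sen, spe, acc, mcc


def metrics_from_rates(
    sen_pct: float, spe_pct: float, n_pos: float, n_neg: float
) -> tuple[float, float]:
    """Reconstruct (Acc%, MCC) from printed Sen/Spe and the class sizes.

    Fractional confusion counts are used so that percentages rounded for
    display still reproduce the accuracy and MCC they were printed with.
    """
    if not (0 <= sen_pct <= 100 and 0 <= spe_pct <= 100):
        raise ValueError("rates must lie in [0, 100]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp = sen_pct * n_pos / 100.0
    tn = spe_pct * n_neg / 100.0
    c = ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    _, _, acc, mcc = metrics_from_counts(c)
    return acc, mcc


def round_half_up(x: float, digits: int = 2) -> float:
    """Display rounding: half away from zero, as performance tables print."""
    if math.isnan(x):
        return x
    q = 10.0**digits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def confusion_at_threshold(
    labels: np.ndarray, scores: np.ndarray, threshold: float
) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=bool)
    calls = np.asarray(scores, dtype=float) >= threshold
    return ConfusionCounts(
        tp=float(np.sum(calls & labels)),
        fp=float(np.sum(calls & ~labels)),
        tn=float(np.sum(~calls & ~labels)),
        fn=float(np.sum(~calls & labels)),
    )


def roc_auc(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points over all distinct score cutoffs and the trapezoidal AUC."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    # keep only the last index of each tied score block
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class EvalReport:
    """Cross-validated performance: per-threshold table, ROC and AUC."""

    thresholds: list[float]
    # averaged over folds: threshold -> (Sen, Spe, Acc, MCC)
    averaged: dict[float, tuple[float, float, float, float]]
    # computed on the pooled out-of-fold scores
    pooled: dict[float, tuple[float, float, float, float]]
    fold_rows: list[dict[float, tuple[float, float, float, float]]]
    fold_sizes: list[tuple[int, int]]  # (n_pos, n_neg) of each test fold
    roc_points: list[tuple[float, float]]
    auc: float
    encoding: str = ""
    window: int = 0
    seed: int = 0

    def best_row(self, by: str = "mcc") -> tuple[float, tuple[float, float, float, float]]:
        """Threshold with maximum MCC (averaged table)."""
        idx = {"sen": 0, "spe": 1, "acc": 2, "mcc": 3}[by]
        t = max(self.averaged, key=lambda t: self.averaged[t][idx])
        return t, self.averaged[t]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# encoding={self.encoding}\twindow={self.window}\t"
                f"seed={self.seed}\tauc={self.auc:.4f}\n"
            )
            fh.write("threshold\tsen\tspe\tacc\tmcc\n")
            for t in self.thresholds:
                sen, spe, acc, mcc = self.averaged[t]
                fh.write(
                    f"{t:+.1f}\t{round_half_up(sen):.2f}\t{round_half_up(spe):.2f}"
                    f"\t{round_half_up(acc):.2f}\t{round_half_up(mcc, 2):.2f}\n"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "encoding": self.encoding,
            "window": self.window,
            "seed": self.seed,
            "auc": self.auc,
            "thresholds": self.thresholds,
            "averaged": {f"{t:+.1f}": list(v) for t, v in self.averaged.items()},
            "pooled": {f"{t:+.1f}": list(v) for t, v in self.pooled.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def roc_to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr,tpr\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr:.6f},{tpr:.6f}\n")


def _threshold_table(
    labels: np.ndarray, scores: np.ndarray, thresholds
) -> dict[float, tuple[float, float, float, float]]:
    return {
        t: metrics_from_counts(confusion_at_threshold(labels, scores, t))
        for t in thresholds
    }


def five_fold_cv(
    dataset: PatternDataset,
    encoding: Encoding,
    config: SvmConfig | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    pssms: dict[str, PSSMMatrix] | None = None,
    n_folds: int = 5,
) -> EvalReport:
    """Stratified k-fold cross-validation of the window SVM.

    Folds preserve the class ratio; each fold is tested once on a model
    trained on the remaining folds.  The per-threshold table is the average
    of the five per-fold tables; ROC/AUC come from the pooled out-of-fold
    scores.
    """
    if config is None:
        config = SvmConfig()
    thresholds = [round(float(t), 10) for t in thresholds]
    y = dataset.labels
    if min(int(y.sum()), int((1 - y).sum())) < n_folds:
        raise ValueError(f"need at least {n_folds} patterns in each class")
    X = encode_patterns(dataset.patterns, encoding, pssms=pssms)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    pooled_scores = np.zeros(len(y), dtype=float)
    fold_rows = []
    fold_sizes = []
    for train_idx, test_idx in skf.split(X, y):
        model = train_on_vectors(
            X[train_idx], y[train_idx], config, encoding, dataset.window
        )
        scores = model.decision_scores(X[test_idx])
        pooled_scores[test_idx] = scores
        fold_rows.append(_threshold_table(y[test_idx], scores, thresholds))
        fold_sizes.append((int(y[test_idx].sum()), int((1 - y[test_idx]).sum())))

    averaged = {
        t: tuple(
            float(np.mean([fold[t][k] for fold in fold_rows])) for k in range(4)
        )
        for t in thresholds
    }
    pooled = _threshold_table(y, pooled_scores, thresholds)
    points, auc = roc_auc(y, pooled_scores)
    return EvalReport(
        thresholds=thresholds,
        averaged=averaged,
        pooled=pooled,
        fold_rows=fold_rows,
        fold_sizes=fold_sizes,
        roc_points=points,
        auc=auc,
        encoding=encoding,
        window=dataset.window,
        seed=config.seed,
    )
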