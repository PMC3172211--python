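"""RBF support-vector machine with asymmetric class cost.

The classifier is parameterized the way sequence-window SVM studies usually
report it: ``g`` (RBF kernel width), ``c`` (trade-off between training error
and margin) and ``j`` (cost factor: errors on positive training examples are
penalized ``j`` times as heavily as errors on negatives).  Predictions are
continuous decision scores (signed margins); a residue is called positive at
threshold t when score >= t, and sweeping t trades sensitivity against
specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .datasets import PatternDataset
from .encoders import Encoding, PSSMMatrix, encode_patterns

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SvmConfig:
    g: float = 0.01  # RBF gamma
    c: float = 2.0  # error/margin trade-off
    j: float = 2.0  # positive-class cost factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g <= 0 or self.c <= 0 or self.j <= 0:
            raise ValueError("g, c and j must all be positive")


@dataclass
class TrainedModel:
    """A fitted SVM plus everything needed to validate and reuse it."""

    config: SvmConfig
    encoding: Encoding
    window: int
    dimension: int
    svc: SVC = field(repr=False)

    def decision_scores(self, vectors: np.ndarray) -> np.ndarray:
        """Signed margin for each row; classification is score >= threshold."""
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim == 1:
            vectors = vectors[None, :]
        if vectors.shape[1] != self.dimension:
            raise ValueError(
                f"feature dimension {vectors.shape[1]} != model dimension "
                f"{self.dimension}"
            )
        return self.svc.decision_function(vectors)

    def predict(self, vectors: np.ndarray, threshold: float = 0.0) -> np.ndarray:
        return (self.decision_scores(vectors) >= threshold).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": _FORMAT_VERSION,
                "config": self.config,
                "encoding": self.encoding,
                "window": self.window,
                "dimension": self.dimension,
                "svc": self.svc,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model file version in {path}")
        return cls(
            config=blob["config"],
            encoding=blob["encoding"],
            window=blob["window"],
            dimension=blob["dimension"],
            svc=blob["svc"],
        )


def train_on_vectors(
    X: np.ndarray, y: np.ndarray, config: SvmConfig, encoding: Encoding, window: int
) -> TrainedModel:
    """Fit the RBF SVM on a prepared design matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(
        kernel="rbf",
        gamma=config.g,
        C=config.c,
        class_weight={1: config.j, 0: 1.0},
        random_state=config.seed,
    )
    svc.fit(X, y)
    return TrainedModel(
        config=config,
        encoding=encoding,
        window=window,
        dimension=X.shape[1],
        svc=svc,
    )


def train(
    dataset: PatternDataset,
    encoding: Encoding,
    config: SvmConfig | None = None,
    pssms: dict[str, PSSMMatrix] | None = None,
) -> TrainedModel:
    """Encode a pattern dataset and fit the SVM on it."""
    if config is None:
        config = SvmConfig()
    X = encode_patterns(dataset.patterns, encoding, pssms=pssms)
    return train_on_vectors(X, dataset.labels, config, encoding, dataset.window)


#: Default hyperparameter grid.  Kernel widths span one-hot scale (where
#: squared distances between windows are O(10)) through composition scale
#: (unit-sum vectors, squared distances O(0.01)).
DEFAULT_GRID: tuple[SvmConfig, ...] = tuple(
    SvmConfig(g=g, c=c, j=j)
    for g in (0.01, 0.1, 1.0, 2.0, 5.0)
    for c in (1.0, 2.0)
    for j in (1.0, 2.0)
)


def grid_search(
    dataset: PatternDataset,
    encoding: Encoding,
    grid: tuple[SvmConfig, ...] = DEFAULT_GRID,
    pssms: dict[str, PSSMMatrix] | None = None,
    seed: int = 0,
    criterion: str = "mcc0",
):
    """Select SVM hyperparameters by five-fold cross-validated performance.

    ``criterion`` is ``"mcc0"`` (MCC at threshold 0, the balanced operating
    point) or ``"auc"``.  Returns (best_config, best_report, all_scores).
    Selection on the same cross-validation folds that are reported follows
    the usual protocol for this kind of study; scores are therefore mildly
    optimistic for unseen chains.
    """
    from dataclasses import replace as _replace

    from .evaluation import five_fold_cv

    best = None
    scores: dict[SvmConfig, float] = {}
    for cfg in grid:
        cfg = _replace(cfg, seed=seed)
        report = five_fold_cv(dataset, encoding, cfg, pssms=pssms)
        score = report.auc if criterion == "auc" else report.averaged[0.0][3]
        scores[cfg] = score
        if best is None or score > best[2]:
            best = (cfg, report, score)
    assert best is not None
    return best[0], best[1], scores
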