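"""RBF-kernel SVM classification of NRS-2002 risk class, plus metrics.

Class convention: subjects with NRS-2002 score < 3 form the *positive*
class (label +1, not at nutritional risk) and subjects with score >= 3 the
*negative* class (label 0, at risk).  All metrics below (precision, recall,
F1) are stated with respect to that positive class.

Default hyperparameters are C = 50, RBF kernel, gamma = 1e-5.  No class
weighting is applied by default; an optional flag enables balanced weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SvmConfig",
    "ConfusionCounts",
    "label_from_score",
    "train_svm",
    "predict",
    "grid_search",
    "confusion",
    "metrics",
]

UNDEFINED = float("nan")


def label_from_score(nrs_score) -> np.ndarray:
    """Map NRS-2002 scores to labels: 1 = positive (score < 3), 0 = negative."""
    scores = np.asarray(nrs_score, dtype=int)
    if ((scores < 0) | (scores > 5)).any():
        raise ValueError("NRS-2002 scores must lie in [0, 5]")
    return (scores < 3).astype(int)


@dataclass(frozen=True)
class SvmConfig:
    C: float = 50.0
    kernel: str = "rbf"
    gamma: float = 1e-5
    seed: int = 0
    balanced: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel not in ("rbf", "linear", "poly", "sigmoid"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.kernel != "linear" and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _make_svc(config: SvmConfig) -> SVC:
    return SVC(
        C=config.C,
        kernel=config.kernel,
        gamma=config.gamma if config.kernel != "linear" else "scale",
        class_weight="balanced" if config.balanced else None,
        random_state=config.seed,
    )


def train_svm(features: np.ndarray, labels: np.ndarray, config: SvmConfig = SvmConfig()) -> SVC:
    """Fit the soft-margin kernel SVM; requires both classes present."""
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features/labels shape mismatch")
    if not np.isfinite(x).all():
        raise ValueError("features contain NaN/inf")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    return _make_svc(config).fit(x, y)


def predict(model: SVC, features: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(features, dtype=np.float64))


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    grid: "dict[str, list]",
    folds: int = 5,
    seed: int = 0,
) -> SvmConfig:
    """Exhaustive cross-validated hyperparameter search.

    ``grid`` maps any of {"C", "gamma", "kernel"} to candidate lists; missing
    keys fall back to the defaults.  Ties in mean fold accuracy are broken
    toward smaller C, then smaller gamma, then kernel order as listed.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(y):
        raise ValueError("more folds than samples")

    cs = list(grid.get("C", [SvmConfig.C]))
    gammas = list(grid.get("gamma", [SvmConfig.gamma]))
    kernels = list(grid.get("kernel", [SvmConfig.kernel]))
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(x, y))

    best: tuple | None = None
    for kernel, c, gamma in product(kernels, cs, gammas):
        config = SvmConfig(C=c, kernel=kernel, gamma=gamma, seed=seed)
        accs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2:
                raise ValueError("a training fold contains a single class")
            model = _make_svc(config).fit(x[tr], y[tr])
            accs.append(float((model.predict(x[te]) == y[te]).mean()))
        score = float(np.mean(accs))
        key = (-score, c, gamma, kernels.index(kernel))
        if best is None or key < best[0]:
            best = (key, config)
    return best[1]


def confusion(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with positive = label 1 (NRS-2002 < 3)."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth/prediction length mismatch")
    if t.size == 0:
        raise ValueError("empty input")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from confusion counts.

    A metric whose denominator is zero is reported as NaN (undefined), never
    silently as 0.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else UNDEFINED

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = UNDEFINED
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
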