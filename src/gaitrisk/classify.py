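"""Fall-risk classification: CFS feature selection, LOOCV random forest.

Correlation-based feature selection (CFS) scores a feature subset S of
size k by the merit

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where ``r_cf`` is the mean absolute feature-class correlation over S and
``r_ff`` the mean absolute pairwise feature-feature correlation — high
when features predict the class but do not duplicate each other.  A
best-first forward search maximizes the merit, stopping after five
consecutive expansions without improvement.  Correlations are Pearson
(point-biserial against the 0/1 fall-risk label); zero-variance features
contribute zero correlation with a warning.

Classification is a random forest (100 trees, sqrt-of-d candidate
features per split, majority vote) evaluated by leave-one-out
cross-validation.  CFS runs inside each fold on the n-1 training members
only, so the held-out participant never influences feature selection.
Fall risk is the positive class.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import InsufficientDataError, ParameterError, ValidationError
from .features import PARTICIPANT_REGISTRY, ParticipantVector


@dataclass
class CfsResult:
    """Outcome of the best-first CFS search."""

    selected: list[str]
    merit: float
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)


@dataclass
class ConfusionMatrix:
    """Counts with rows = actual (no fall risk / fall risk), columns = predicted."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def as_dict(self) -> dict[str, int]:
        return {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp}


@dataclass
class ClassificationReport:
    """LOOCV outcome: matrix, metrics, per-fold selections, provenance."""

    matrix: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    fold_features: list[list[str]]
    seed: int
    config: dict

    def as_dict(self) -> dict:
        return {
            "matrix": self.matrix.as_dict(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_pct": round(self.accuracy * 100, 1),
            "sensitivity_pct": round(self.sensitivity * 100, 1),
            "specificity_pct": round(self.specificity * 100, 1),
            "fold_features": self.fold_features,
            "seed": self.seed,
            "config": self.config,
        }


def confusion_metrics(m: ConfusionMatrix) -> tuple[float, float, float]:
    """Accuracy, sensitivity (fall-risk recall), specificity as proportions.

    Computed with exact rational arithmetic and converted to float at the
    end; undefined margins (no positives or no negatives) raise.
    """
    if m.total == 0:
        raise ValidationError("empty confusion matrix")
    if m.tp + m.fn == 0 or m.tn + m.fp == 0:
        raise ValidationError("a class margin is empty; metric undefined")
    accuracy = Fraction(m.tn + m.tp, m.total)
    sensitivity = Fraction(m.tp, m.tp + m.fn)
    specificity = Fraction(m.tn, m.tn + m.fp)
    return float(accuracy), float(sensitivity), float(specificity)


def metrics_percent(m: ConfusionMatrix, digits: int = 1) -> tuple[float, float, float]:
    """The three metrics as percentages rounded to ``digits`` decimals."""
    return tuple(round(v * 100, digits) for v in confusion_metrics(m))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# correlation-based feature selection

def _abs_correlations(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|Pearson| feature-class vector and feature-feature matrix.

    Zero-variance columns get zero correlation everywhere (warned once).
    """
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance feature(s); correlations set to 0",
            stacklevel=3,
        )
    sd_safe = np.where(dead, 1.0, sd)
    Z = Xc / sd_safe
    Z[:, dead] = 0.0
    yc = y - y.mean()
    y_sd = yc.std()
    if y_sd == 0:
        r_cf = np.zeros(X.shape[1])
    else:
        r_cf = np.abs(Z.T @ (yc / y_sd)) / X.shape[0]
    r_ff = np.abs(Z.T @ Z) / X.shape[0]
    np.fill_diagonal(r_ff, 1.0)
    r_ff[dead, :] = 0.0
    r_ff[:, dead] = 0.0
    return r_cf, r_ff


def merit_from_correlations(k: int, r_cf: float, r_ff: float) -> float:
    """CFS merit of a size-k subset with the given mean correlations."""
    if k < 1:
        raise ParameterError("subset size must be >= 1")
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def cfs_merit(
    subset: list[str],
    vectors: list[ParticipantVector],
    feature_names: list[str] | None = None,
) -> float:
    """Merit of a named feature subset on a participant table."""
    if not subset:
        raise ParameterError("subset must be non-empty")
    names = list(feature_names or PARTICIPANT_REGISTRY)
    idx = [names.index(f) for f in subset]
    X = np.array([v.values for v in vectors], dtype=float)
    y = np.array([v.fall_risk for v in vectors], dtype=float)
    r_cf, r_ff = _abs_correlations(X, y)
    return _subset_merit(np.array(idx), r_cf, r_ff)


def _subset_merit(idx: np.ndarray, r_cf: np.ndarray, r_ff: np.ndarray) -> float:
    k = idx.size
    mean_cf = float(r_cf[idx].mean())
    if k == 1:
        return merit_from_correlations(1, mean_cf, 0.0)
    sub = r_ff[np.ix_(idx, idx)]
    mean_ff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return merit_from_correlations(k, mean_cf, mean_ff)


def cfs_select(
    vectors: list[ParticipantVector],
    feature_names: list[str] | None = None,
    patience: int = 5,
) -> CfsResult:
    """Best-first forward search over feature subsets maximizing the merit.

    Starts from the single best feature and repeatedly expands the most
    promising open subset by one feature; stops after ``patience``
    consecutive expansions that fail to improve the best merit found.
    Deterministic given the data (ties broken by registry order).
    """
    names = list(feature_names or PARTICIPANT_REGISTRY)
    X = np.array([v.values for v in vectors], dtype=float)
    y = np.array([v.fall_risk for v in vectors], dtype=float)
    if X.shape[1] < 2:
        raise ParameterError("CFS needs at least 2 features")
    r_cf, r_ff = _abs_correlations(X, y)
    if not np.any(r_cf > 0):
        warnings.warn("all features uncorrelated with the class; empty selection",
                      stacklevel=2)
        return CfsResult(selected=[], merit=0.0)

    d = X.shape[1]
    trace: list[tuple[tuple[str, ...], float]] = []
    # open list keyed by -merit; counter breaks ties deterministically
    best_subset = (int(np.argmax(r_cf)),)
    best_merit = _subset_merit(np.array(best_subset), r_cf, r_ff)
    open_heap: list[tuple[float, int, tuple[int, ...]]] = [(-best_merit, 0, best_subset)]
    visited = {best_subset}
    counter = 1
    stale = 0
    while open_heap and stale < patience:
        neg_merit, _, subset = heapq.heappop(open_heap)
        trace.append((tuple(names[i] for i in subset), -neg_merit))
        improved = False
        for f in range(d):
            if f in subset:
                continue
            child = tuple(sorted((*subset, f)))
            if child in visited:
                continue
            visited.add(child)
            merit = _subset_merit(np.array(child), r_cf, r_ff)
            heapq.heappush(open_heap, (-merit, counter, child))
            counter += 1
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_subset = child
                improved = True
        stale = 0 if improved else stale + 1
    return CfsResult(
        selected=[names[i] for i in best_subset], merit=best_merit, trace=trace
    )


# ---------------------------------------------------------------------------
# leave-one-out random forest

@dataclass
class ForestConfig:
    n_trees: int = 100
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    cfs_patience: int = 5


def loocv_random_forest(
    vectors: list[ParticipantVector],
    config: ForestConfig | None = None,
    seed: int = 0,
) -> ClassificationReport:
    """Leave-one-out evaluation with fold-internal feature selection.

    For every participant: run CFS on the remaining n-1, train a random
    forest on the selected features, predict the held-out member.  The
    confusion matrix accumulates the n held-out predictions.  Fixed seed
    gives an identical report.
    """
    config = config or ForestConfig()
    y = np.array([v.fall_risk for v in vectors], dtype=int)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise InsufficientDataError(
            "LOOCV needs at least 2 members of each fall-risk class"
        )
    X = np.array([v.values for v in vectors], dtype=float)
    names = list(PARTICIPANT_REGISTRY)
    n = len(vectors)
    tn = fp = fn = tp = 0
    fold_features: list[list[str]] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = [vectors[j] for j in range(n) if mask[j]]
        sel = cfs_select(train, names, patience=config.cfs_patience)
        selected = sel.selected or names  # degenerate fold: keep everything
        idx = [names.index(f) for f in selected]
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.max_features,
            max_depth=config.max_depth,
            random_state=seed,
        )
        forest.fit(X[mask][:, idx], y[mask])
        pred = int(forest.predict(X[i : i + 1, idx])[0])
        fold_features.append(selected)
        if y[i] == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred
    matrix = ConfusionMatrix(tn=tn, fp=fp, fn=fn, tp=tp)
    acc, sens, spec = confusion_metrics(matrix)
    return ClassificationReport(
        matrix=matrix,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        fold_features=fold_features,
        seed=seed,
        config={
            "n_trees": config.n_trees,
            "max_features": config.max_features,
            "max_depth": config.max_depth,
            "cfs_patience": config.cfs_patience,
        },
    )
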