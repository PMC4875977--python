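"""Weighted-voting ensemble of the three basic classifiers.

For a superfamily S_j the ensemble score of a query protein P is

    C_{S_j}(P) = sum_{i=1..3} w_{iS_j} * C_{iS_j}(P, S_j)

where C_{iS_j}(P, S_j) in [0, 1] is the i-th basic classifier's normalized
belief that P belongs to S_j and w_{iS_j} is that classifier's weight: its
average ROC score on S_j.  Weights are estimated honestly by stratified
k-fold cross-validation on the task's *training* data (estimating them on
the test set would leak labels; that "oracle" variant is kept behind a flag
for comparison).  Weights are applied raw — they are ROC scores in [0, 1]
and are deliberately not renormalized to sum to 1.

A query is assigned to the superfamily whose ensemble score is highest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluate import roc_score
from .model import (
    DEFAULT_C,
    DEFAULT_GAMMA,
    FamilyTask,
    TrainedBasicClassifier,
    _stack,
    normalize_scores,
    score,
    train_basic,
)


class FoldError(ValueError):
    """Not enough samples per class for the requested fold count."""


class ConfigurationError(ValueError):
    """An ensemble model is structurally unusable."""


@dataclass
class EnsembleModel:
    """Per-superfamily basic classifiers and their voting weights."""

    superfamilies: dict[str, tuple[dict[str, TrainedBasicClassifier], dict[str, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for sf, (clfs, weights) in self.superfamilies.items():
            for scheme, w in weights.items():
                if not (np.isfinite(w) and 0.0 <= w <= 1.0):
                    raise ConfigurationError(
                        f"superfamily {sf!r}, scheme {scheme!r}: weight {w} outside [0, 1]"
                    )


def estimate_weights(
    task: FamilyTask,
    scheme_vectors: Mapping[str, Mapping[str, np.ndarray]],
    folds: int = 3,
    seed: int = 0,
    C: float = DEFAULT_C,
    gamma: float | str = DEFAULT_GAMMA,
) -> dict[str, float]:
    """Per-scheme weights: mean ROC over stratified CV folds of the training set."""
    if folds < 2:
        raise FoldError("folds must be >= 2")
    n_pos, n_neg = len(task.train_pos), len(task.train_neg)
    if min(n_pos, n_neg) < folds:
        raise FoldError(
            f"family {task.family_id!r}: {folds}-fold CV needs >= {folds} samples per class "
            f"(have {n_pos} positives, {n_neg} negatives)"
        )
    y = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    weights: dict[str, float] = {}
    for scheme, vectors in scheme_vectors.items():
        X = _stack(vectors, task.train_ids)
        fold_rocs = []
        for train_idx, val_idx in splitter.split(X, y):
            svm = SVC(kernel="rbf", C=C, gamma=gamma)
            svm.fit(X[train_idx], y[train_idx])
            decision = svm.decision_function(X[val_idx])
            yv = y[val_idx]
            fold_rocs.append(roc_score(decision[yv > 0], decision[yv < 0]))
        weights[scheme] = float(np.mean(fold_rocs))
    return weights


def oracle_weights(
    task: FamilyTask,
    classifiers: Mapping[str, TrainedBasicClassifier],
    scheme_vectors: Mapping[str, Mapping[str, np.ndarray]],
) -> dict[str, float]:
    """Weights from test-set ROC (label-leaking; kept only for comparison)."""
    weights = {}
    for scheme, clf in classifiers.items():
        raw = score(clf, scheme_vectors[scheme], task.test_ids)
        weights[scheme] = roc_score(
            [raw[i] for i in task.test_pos], [raw[i] for i in task.test_neg]
        )
    return weights


def train_task_ensemble(
    task: FamilyTask,
    scheme_vectors: Mapping[str, Mapping[str, np.ndarray]],
    folds: int = 3,
    seed: int = 0,
    weights_from: str = "cv",
    C: float = DEFAULT_C,
    gamma: float | str = DEFAULT_GAMMA,
) -> tuple[dict[str, TrainedBasicClassifier], dict[str, float]]:
    """Train one basic classifier per scheme for the task and estimate weights."""
    classifiers = {
        scheme: train_basic(task, vectors, scheme=scheme, C=C, gamma=gamma)
        for scheme, vectors in scheme_vectors.items()
    }
    if weights_from == "cv":
        weights = estimate_weights(task, scheme_vectors, folds=folds, seed=seed, C=C, gamma=gamma)
    elif weights_from == "oracle":
        weights = oracle_weights(task, classifiers, scheme_vectors)
    else:
        raise ValueError("weights_from must be 'cv' or 'oracle'")
    return classifiers, weights


def ensemble_score(scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted sum of the basic classifiers' normalized belief values."""
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if scores.shape != weights.shape:
        raise ValueError("scores and weights must have matching length")
    return float(np.dot(weights, scores))


def build_superfamily_model(
    tasks: Sequence[FamilyTask],
    scheme_vectors: Mapping[str, Mapping[str, np.ndarray]],
    folds: int = 3,
    seed: int = 0,
    weights_from: str = "cv",
) -> EnsembleModel:
    """One trained task ensemble per superfamily (the lexicographically first
    family of each superfamily represents it)."""
    chosen: dict[str, FamilyTask] = {}
    for task in sorted(tasks, key=lambda t: t.family_id):
        chosen.setdefault(task.superfamily_id, task)
    superfamilies = {}
    for sf, task in chosen.items():
        clfs, weights = train_task_ensemble(
            task, scheme_vectors, folds=folds, seed=seed, weights_from=weights_from
        )
        superfamilies[sf] = (clfs, weights)
    return EnsembleModel(superfamilies=superfamilies)


def superfamily_scores(
    seq_id: str,
    model: EnsembleModel,
    scheme_vectors: Mapping[str, Mapping[str, np.ndarray]],
) -> dict[str, float]:
    """The ensemble score of one query against every superfamily in the model."""
    if not model.superfamilies:
        raise ConfigurationError("ensemble model has no superfamilies")
    out = {}
    for sf, (clfs, weights) in model.superfamilies.items():
        beliefs = []
        ws = []
        for scheme in sorted(clfs):
            raw = score(clfs[scheme], scheme_vectors[scheme], [seq_id])
            norm = normalize_scores(raw, clfs[scheme].bounds)
            beliefs.append(norm[seq_id])
            ws.append(weights[scheme])
        out[sf] = ensemble_score(beliefs, ws)
    return out


def assign_superfamily(
    seq_id: str,
    model: EnsembleModel,
    scheme_vectors: Mapping[str, Mapping[str, np.ndarray]],
) -> str:
    """Argmax of the per-superfamily ensemble scores; ties break to the
    lexicographically smallest superfamily id."""
    scores_by_sf = superfamily_scores(seq_id, model, scheme_vectors)
    best_sf, best = None, -np.inf
    for sf in sorted(scores_by_sf):
        if scores_by_sf[sf] > best:
            best_sf, best = sf, scores_by_sf[sf]
    return best_sf
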