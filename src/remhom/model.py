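"""Per-family SVM basic classifiers.

The benchmark is organised as one binary task per held-out family: positives
are proteins of the family's superfamily (the family itself held out for
testing, sibling families used for training), negatives come from other
folds.  A *basic classifier* is an RBF-kernel SVM trained on one feature
scheme for one task; its decision values are min-max normalized to [0, 1]
using the training pool's score range so that classifiers built on different
schemes become commensurable before ensemble voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

#: Pinned SVM defaults: RBF kernel, C = 1, gamma = 1 / (n_features * Var(X)).
DEFAULT_C = 1.0
DEFAULT_GAMMA = "scale"

ROLES = ("train-pos", "train-neg", "test-pos", "test-neg")


class TaskError(ValueError):
    """A family task violates its structural contract."""


@dataclass(frozen=True)
class FamilyTask:
    """One held-out family's train/test split within its superfamily."""

    family_id: str
    superfamily_id: str
    train_pos: tuple[str, ...]
    train_neg: tuple[str, ...]
    test_pos: tuple[str, ...]
    test_neg: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_pos), set(self.train_neg), set(self.test_pos), set(self.test_neg)]
        n_total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != n_total:
            raise TaskError(f"family {self.family_id!r}: the four roles overlap")
        if not self.train_pos:
            raise TaskError(f"family {self.family_id!r}: empty positive training set")
        if not self.train_neg:
            raise TaskError(f"family {self.family_id!r}: empty negative training set")

    @property
    def train_ids(self) -> tuple[str, ...]:
        return self.train_pos + self.train_neg

    @property
    def test_ids(self) -> tuple[str, ...]:
        return self.test_pos + self.test_neg


@dataclass
class TrainedBasicClassifier:
    """A fitted basic classifier plus its score-normalization bounds."""

    scheme: str
    task: FamilyTask
    svm: SVC = field(repr=False)
    bounds: tuple[float, float]
    dimension: int


def _stack(vectors: Mapping[str, np.ndarray], ids: Iterable[str]) -> np.ndarray:
    rows = []
    for sid in ids:
        try:
            rows.append(np.asarray(vectors[sid], dtype=float))
        except KeyError:
            raise KeyError(f"no feature vector for sequence id {sid!r}") from None
    dims = {r.shape for r in rows}
    if len(dims) > 1:
        raise ValueError(f"feature vectors have mismatched dimensions: {sorted(dims)}")
    return np.vstack(rows)


def train_basic(
    task: FamilyTask,
    vectors: Mapping[str, np.ndarray],
    scheme: str = "",
    C: float = DEFAULT_C,
    gamma: float | str = DEFAULT_GAMMA,
    class_weight: str | None = None,
) -> TrainedBasicClassifier:
    """Fit an RBF-kernel SVM on the task's training pool.

    Training is deterministic for fixed inputs and parameters.  The min/max
    of the decision values over the training pool are stored for later
    normalization.  ``class_weight='balanced'`` opts into imbalance
    reweighting (off by default).
    """
    X = _stack(vectors, task.train_ids)
    y = np.concatenate([np.ones(len(task.train_pos)), -np.ones(len(task.train_neg))])
    svm = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
    svm.fit(X, y)
    decision = svm.decision_function(X)
    bounds = (float(decision.min()), float(decision.max()))
    return TrainedBasicClassifier(
        scheme=scheme, task=task, svm=svm, bounds=bounds, dimension=X.shape[1]
    )


def score(
    clf: TrainedBasicClassifier,
    vectors: Mapping[str, np.ndarray],
    ids: Iterable[str],
) -> dict[str, float]:
    """Raw SVM decision values; higher means more family-like."""
    ids = list(ids)
    if not ids:
        return {}
    X = _stack(vectors, ids)
    if X.shape[1] != clf.dimension:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match trained dimension {clf.dimension}"
        )
    decision = clf.svm.decision_function(X)
    return {sid: float(v) for sid, v in zip(ids, decision)}


def normalize_scores(
    raw: Mapping[str, float], bounds: tuple[float, float]
) -> dict[str, float]:
    """Min-max scale into [0, 1] with clipping; degenerate bounds map to 0.5."""
    lo, hi = bounds
    if hi == lo:
        return {sid: 0.5 for sid in raw}
    span = hi - lo
    return {sid: float(np.clip((v - lo) / span, 0.0, 1.0)) for sid, v in raw.items()}


# ---------------------------------------------------------------------------
# Split table I/O
# ---------------------------------------------------------------------------

def read_split(path: str | Path) -> pd.DataFrame:
    """Read a benchmark split table: family_id, superfamily_id, seq_id, role."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "superfamily_id", "seq_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise TaskError(f"split table missing columns {sorted(missing)}")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise TaskError(f"unknown roles {sorted(bad)}; expected {ROLES}")
    return df


def write_split(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def tasks_from_split(df: pd.DataFrame) -> list[FamilyTask]:
    """Materialize one :class:`FamilyTask` per family in the split table."""
    tasks = []
    for family_id, grp in df.groupby("family_id", sort=True):
        superfamilies = grp.loc[grp["role"].str.endswith("pos"), "superfamily_id"].unique()
        if len(superfamilies) != 1:
            raise TaskError(f"family {family_id!r}: positives span {len(superfamilies)} superfamilies")
        by_role = {role: tuple(grp.loc[grp["role"] == role, "seq_id"]) for role in ROLES}
        tasks.append(
            FamilyTask(
                family_id=str(family_id),
                superfamily_id=str(superfamilies[0]),
                train_pos=by_role["train-pos"],
                train_neg=by_role["train-neg"],
                test_pos=by_role["test-pos"],
                test_neg=by_role["test-neg"],
            )
        )
    return tasks


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_classifier(clf: TrainedBasicClassifier, path: str | Path) -> None:
    joblib.dump(clf, path)


def load_classifier(path: str | Path) -> TrainedBasicClassifier:
    return joblib.load(path)
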