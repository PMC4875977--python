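"""ROC / ROC50 metrics and the per-family benchmark harness.

The benchmark's test pools are heavily imbalanced (few positives, many
negatives), so performance is reported as ranking quality:

* **ROC score** — the normalized area under the curve of true positives
  against false positives, equal to the Mann-Whitney statistic: the fraction
  of (positive, negative) pairs in which the positive outranks the negative,
  with ties counted 1/2.  1 means perfect separation, 0.5 random.
* **ROC50 score** — the area under the ROC curve up to the 50th false
  positive, normalized by n_pos * min(50, n_neg) so it also lies in [0, 1];
  it emphasizes early retrieval.  When there are at most 50 negatives the
  truncation is vacuous and ROC50 equals ROC.  At equal scores the curve is
  built pessimistically (negatives ranked ahead of positives), which avoids
  inflating the truncated metric.

The benchmark harness trains one classifier (or the weighted ensemble) per
held-out family, scores that family's test pool and reports per-family
ROC/ROC50 plus unweighted means across families.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class EvaluationError(ValueError):
    """Scores cannot be evaluated (e.g. an empty class)."""


@dataclass(frozen=True)
class RocResult:
    roc: float
    roc50: float
    n_pos: int
    n_neg: int


def roc_score(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann-Whitney ROC: fraction of (pos, neg) pairs with pos > neg, ties 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both positive and negative score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))  # average ranks handle ties as 1/2
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc50_score(
    pos_scores: Sequence[float], neg_scores: Sequence[float], n_fp: int = 50
) -> float:
    """ROC area truncated at the ``n_fp``-th false positive, in [0, 1].

    Scores are ranked descending with ties resolved pessimistically
    (negatives before positives at equal score).  The area is the number of
    (pos, neg) pairs won among the top min(n_fp, n_neg) negatives, normalized
    by n_pos * min(n_fp, n_neg).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both positive and negative score lists must be nonempty")
    scores = np.concatenate([pos, neg])
    is_pos = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    # descending by score; at equal scores negatives first (pessimistic)
    order = np.lexsort((is_pos, -scores))
    limit = min(n_fp, neg.size)
    tp = 0
    area = 0
    fp = 0
    for idx in order:
        if is_pos[idx]:
            tp += 1
        else:
            fp += 1
            area += tp
            if fp == limit:
                break
    return float(area / (pos.size * limit))


def roc_result(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> RocResult:
    return RocResult(
        roc=roc_score(pos_scores, neg_scores),
        roc50=roc50_score(pos_scores, neg_scores),
        n_pos=len(pos_scores),
        n_neg=len(neg_scores),
    )


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

from .features import SCHEMES, encode_all  # noqa: E402  (metric defs first)
from .model import FamilyTask, normalize_scores, score  # noqa: E402


def collect_task_scores(
    tasks: Sequence[FamilyTask],
    scheme_vectors: Mapping[str, Mapping[str, np.ndarray]],
    folds: int = 3,
    seed: int = 0,
    weights_from: str = "cv",
) -> list[dict]:
    """Train every scheme on every task and collect normalized test scores.

    Returns one record per usable task with the per-scheme normalized scores
    of the test pool and the per-scheme CV weights; families without test
    positives or negatives are skipped with a warning.  Any subset of schemes
    can then be combined into an ensemble without retraining.
    """
    from .ensemble import train_task_ensemble  # local import avoids a cycle

    records = []
    for task in tasks:
        if not task.test_pos or not task.test_neg:
            warnings.warn(
                f"family {task.family_id!r} lacks test positives or negatives; skipped",
                stacklevel=2,
            )
            continue
        classifiers, weights = train_task_ensemble(
            task, scheme_vectors, folds=folds, seed=seed, weights_from=weights_from
        )
        norm_scores = {}
        for scheme, clf in classifiers.items():
            raw = score(clf, scheme_vectors[scheme], task.test_ids)
            norm_scores[scheme] = normalize_scores(raw, clf.bounds)
        records.append(
            {
                "task": task,
                "weights": weights,
                "scores": norm_scores,
            }
        )
    return records


def _combined_result(record: dict, schemes: Sequence[str]) -> RocResult:
    task: FamilyTask = record["task"]
    combined = {
        sid: sum(record["weights"][s] * record["scores"][s][sid] for s in schemes)
        for sid in task.test_ids
    }
    return roc_result(
        [combined[i] for i in task.test_pos], [combined[i] for i in task.test_neg]
    )


def tabulate(records: Sequence[dict], schemes: Sequence[str]) -> pd.DataFrame:
    """Per-family ROC/ROC50 for a scheme combination (weighted if > 1 scheme)."""
    rows = []
    for rec in records:
        task: FamilyTask = rec["task"]
        if len(schemes) == 1:
            s = schemes[0]
            res = roc_result(
                [rec["scores"][s][i] for i in task.test_pos],
                [rec["scores"][s][i] for i in task.test_neg],
            )
        else:
            res = _combined_result(rec, schemes)
        rows.append(
            {
                "family": task.family_id,
                "superfamily": task.superfamily_id,
                "n_pos_test": res.n_pos,
                "n_neg_test": res.n_neg,
                "roc": res.roc,
                "roc50": res.roc50,
            }
        )
    return pd.DataFrame(rows)


def run_benchmark(
    split: pd.DataFrame,
    sequences,
    schemes: Sequence[str] = ("kmer",),
    configs: Mapping[str, object] | None = None,
    folds: int = 3,
    seed: int = 0,
    weights_from: str = "cv",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Run the per-family benchmark for one scheme or a weighted ensemble.

    Returns the per-family table plus unweighted means across families.
    """
    from .model import tasks_from_split

    configs = configs or {}
    tasks = tasks_from_split(split)
    scheme_vectors = {
        s: encode_all(sequences, s, configs.get(s)) for s in schemes
    }
    records = collect_task_scores(
        tasks, scheme_vectors, folds=folds, seed=seed, weights_from=weights_from
    )
    table = tabulate(records, schemes)
    summary = {
        "mean_roc": float(table["roc"].mean()),
        "mean_roc50": float(table["roc50"].mean()),
        "n_families": int(len(table)),
    }
    return table, summary


def grid_search(
    split: pd.DataFrame,
    sequences,
    scheme: str,
    grid: Sequence[Mapping[str, object]],
    folds: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Exhaustively evaluate a parameter grid for one scheme.

    Each grid point is a mapping of config-field overrides (e.g. ``{"k": 2}``
    or ``{"lam": 5, "w": 0.2}``).  A grid point whose encoding fails (e.g.
    λ ≥ L − 1 for some sequence) is marked failed and the search continues.
    The best row by mean ROC is flagged.
    """
    from .features import AccConfig, KmerConfig, PseaacConfig

    if not grid:
        raise EvaluationError("parameter grid is empty")
    cfg_cls = {"kmer": KmerConfig, "acc": AccConfig, "sc-pseaac": PseaacConfig}[scheme]
    rows = []
    for params in grid:
        row: dict[str, object] = {"params": dict(params)}
        try:
            cfg = cfg_cls(**params)
            _, summary = run_benchmark(
                split, sequences, schemes=(scheme,), configs={scheme: cfg},
                folds=folds, seed=seed,
            )
            row.update(
                mean_roc=summary["mean_roc"],
                mean_roc50=summary["mean_roc50"],
                failed=False,
            )
        except (ValueError, KeyError) as exc:
            row.update(mean_roc=np.nan, mean_roc50=np.nan, failed=True, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table.loc[~table["failed"], "mean_roc"]
    table["best"] = False
    if not ok.empty:
        table.loc[ok.idxmax(), "best"] = True
    return table


def all_scheme_combinations(schemes: Sequence[str] = SCHEMES) -> list[tuple[str, ...]]:
    """All nonempty subsets of the schemes, singletons first."""
    out = []
    for r in range(1, len(schemes) + 1):
        out.extend(itertools.combinations(schemes, r))
    return out
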