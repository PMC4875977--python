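"""Shared fixtures and independent naive-loop oracles.

The oracles re-derive each encoder and metric definition with plain Python
loops, written directly from the defining formulas; they are deliberately
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import remhom as rh
from remhom.evaluate import collect_task_scores, tabulate
from remhom.seqio import ALPHABET


# ---------------------------------------------------------------------------
# Random sequences
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, length: int, sid: str = "s") -> rh.ProteinSequence:
    residues = "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))
    return rh.ProteinSequence(id=sid, residues=residues)


# ---------------------------------------------------------------------------
# Naive encoder oracles (loop transcriptions of the definitions)
# ---------------------------------------------------------------------------

def kmer_oracle(residues: str, k: int) -> np.ndarray:
    windows = [residues[i : i + k] for i in range(len(residues) - k + 1)]
    windows = [w for w in windows if "X" not in w]
    vec = np.zeros(20**k)
    for w in windows:
        idx = 0
        for ch in w:
            idx = idx * 20 + ALPHABET.index(ch)
        vec[idx] += 1
    return vec / len(windows) if windows else vec


def acc_oracle(residues: str, max_lag: int, index_set=None) -> np.ndarray:
    """Direct double-loop auto/cross covariance with (L - lag) denominators."""
    if index_set is None:
        index_set = rh.PhysChemIndexSet.default()
    L = len(residues)
    n = index_set.n
    P = [[index_set.normalized[u, ALPHABET.index(r)] for r in residues] for u in range(n)]
    means = [sum(P[u]) / L for u in range(n)]
    out = []
    for lag in range(1, max_lag + 1):
        for u1 in range(n):
            for u2 in range(n):
                s = sum(
                    (P[u1][i] - means[u1]) * (P[u2][i + lag] - means[u2])
                    for i in range(L - lag)
                )
                out.append(s / (L - lag))
    return np.array(out)


def tau_oracle(residues: str, lam: int, index_set=None) -> np.ndarray:
    """Tiered correlation factors: nested-loop means of standardized products."""
    if index_set is None:
        index_set = rh.PhysChemIndexSet.default()
    L = len(residues)
    vals = index_set.normalized
    taus = []
    for d in range(1, lam + 1):
        for u in range(3):
            s = sum(
                vals[u, ALPHABET.index(residues[i])] * vals[u, ALPHABET.index(residues[i + d])]
                for i in range(L - d)
            )
            taus.append(s / (L - d))
    return np.array(taus)


def pseaac_oracle(residues: str, lam: int, w: float, index_set=None) -> np.ndarray:
    """From-scratch scalar pseudo amino acid composition."""
    L = len(residues)
    freqs = np.array([residues.count(aa) / L for aa in ALPHABET])
    taus = tau_oracle(residues, lam, index_set)
    denom = freqs.sum() + w * taus.sum()
    return np.concatenate([freqs, w * taus]) / denom


# ---------------------------------------------------------------------------
# Metric oracles
# ---------------------------------------------------------------------------

def roc_pair_oracle(pos, neg) -> float:
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def roc50_pair_oracle(pos, neg, n_fp: int = 50) -> float:
    """Pair-counting form: for each of the top min(n_fp, n_neg) negatives,
    count positives strictly above it (pessimistic ties)."""
    m = min(n_fp, len(neg))
    top_neg = sorted(neg, reverse=True)[:m]
    area = sum(sum(1 for p in pos if p > q) for q in top_neg)
    return area / (len(pos) * m)


# ---------------------------------------------------------------------------
# Heavy shared fixture: full default benchmarks, seeds 1..5
# ---------------------------------------------------------------------------

ALL_COMBOS = [
    ("kmer",),
    ("acc",),
    ("sc-pseaac",),
    ("kmer", "acc"),
    ("kmer", "sc-pseaac"),
    ("acc", "sc-pseaac"),
    ("kmer", "acc", "sc-pseaac"),
]


@pytest.fixture(scope="session")
def benchmark_runs():
    """Per-family tables for every scheme combination on the default synthetic
    benchmark, seeds 1..5.  Generated once per session; several tests and the
    acceptance checks read different slices of it."""
    runs = {}
    for seed in range(1, 6):
        cfg = rh.SynthConfig(seed=seed)
        seqs, split = rh.generate_benchmark(cfg)
        scheme_vectors = {s: rh.encode_all(seqs, s) for s in rh.SCHEMES}
        tasks = rh.tasks_from_split(split)
        records = collect_task_scores(tasks, scheme_vectors, folds=3, seed=seed)
        runs[seed] = {combo: tabulate(records, combo) for combo in ALL_COMBOS}
    return runs
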