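"""Fixed-length feature encodings of protein sequences.

Three encoders turn a variable-length protein into a fixed-length real
vector, each capturing a different view of the sequence:

* **Kmer** — occurrence frequencies of all 20^k length-k residue windows
  (sequence composition; k = 2 by default).
* **ACC** (auto-cross covariance) — lagged covariances of physicochemical
  property signals along the sequence.  For properties u1, u2 and a lag d,

      AC(u, d)       = sum_{i=1..L-d} (P_u(R_i) - mean_u)(P_u(R_{i+d}) - mean_u) / (L - d)
      CC(u1, u2, d)  = sum_{i=1..L-d} (P_u1(R_i) - mean_u1)(P_u2(R_{i+d}) - mean_u2) / (L - d)

  where P_u(R) is the (standardized) property value of residue R and mean_u
  its average along the sequence.  With N = 3 properties and lags 1..LAG the
  vector has N*N*LAG components (126 at LAG = 14).
* **SC-PseAAC** (series-correlation pseudo amino acid composition) — the 20
  amino-acid frequencies f_u plus 3λ tiered correlation factors τ_j, jointly
  normalized:

      x_u      = f_u       / (sum_i f_i + w * sum_j τ_j)   for u = 1..20
      x_{20+j} = w * τ_j   / (sum_i f_i + w * sum_j τ_j)   for j = 1..3λ

  Tier d contributes three factors: the means over i of
  ĥ1(R_i)ĥ1(R_{i+d}), ĥ2(R_i)ĥ2(R_{i+d}) and m̂(R_i)m̂(R_{i+d}),
  where ĥ1, ĥ2, m̂ are hydrophobicity, hydrophilicity and side-chain mass
  standardized to zero mean / unit population variance over the 20 residues.

All three property lookups (ACC and SC-PseAAC) use the standardized values,
which makes the three indices commensurable.  Windows or residue pairs that
span a sentinel residue (ambiguity code) are excluded from the counts, and
denominators shrink accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import ALPHABET, AA_TO_INDEX, SENTINEL, ProteinSequence


class SequenceTooShortError(ValueError):
    """Sequence shorter than the encoder's minimum usable length."""


class DegenerateIndexError(ValueError):
    """A physicochemical index with zero variance cannot be standardized."""


class DegenerateEncodingError(ValueError):
    """The joint normalization denominator is nonpositive."""


# ---------------------------------------------------------------------------
# Physicochemical indices
# ---------------------------------------------------------------------------

#: Canonical hydrophobicity (Tanford/Chou), hydrophilicity (Hopp-Woods) and
#: side-chain mass values, keyed in the ALPHABET order ACDEFGHIKLMNPQRSTVWY.
_DEFAULT_RAW = {
    "hydrophobicity": [
        0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38, -1.50, 1.06,
        0.64, -0.78, 0.12, -0.85, -2.53, -0.18, -0.05, 1.08, 0.81, 0.26,
    ],
    "hydrophilicity": [
        -0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
        -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3,
    ],
    "mass": [
        15.0, 47.0, 59.0, 73.0, 91.0, 1.0, 82.0, 57.0, 73.0, 57.0,
        75.0, 58.0, 42.0, 72.0, 101.0, 31.0, 45.0, 43.0, 130.0, 107.0,
    ],
}

INDEX_NAMES = ("hydrophobicity", "hydrophilicity", "mass")


def normalize_index(raw: Sequence[float]) -> np.ndarray:
    """Standardize 20 per-residue values to zero mean and unit population
    variance (divide by the root mean squared deviation, not the sample SD)."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (20,):
        raise ValueError("an index must provide exactly 20 values")
    centered = raw - raw.mean()
    denom = np.sqrt(np.mean(centered**2))
    # guard against an exactly or numerically constant index
    if denom <= 1e-10 * (np.abs(raw).max() + 1e-30):
        raise DegenerateIndexError("constant index cannot be standardized")
    return centered / denom


@dataclass(frozen=True)
class PhysChemIndexSet:
    """The N = 3 physicochemical indices used by ACC and SC-PseAAC."""

    names: tuple[str, ...]
    raw: np.ndarray  # (N, 20)
    normalized: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        object.__setattr__(self, "raw", raw)
        if raw.shape != (len(self.names), 20):
            raise ValueError("raw values must be (n_indices, 20)")
        norm = np.vstack([normalize_index(r) for r in raw])
        object.__setattr__(self, "normalized", norm)

    @property
    def n(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls) -> "PhysChemIndexSet":
        return cls(
            names=INDEX_NAMES,
            raw=np.array([_DEFAULT_RAW[name] for name in INDEX_NAMES]),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhysChemIndexSet":
        """Load an override table: 20 rows ``residue<TAB>h1<TAB>h2<TAB>mass``
        (a header line starting with a non-residue token is allowed)."""
        rows: dict[str, list[float]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].upper() not in AA_TO_INDEX:
                    continue  # header
                if len(parts) != 4:
                    raise ValueError(f"expected 4 fields per row, got {len(parts)}")
                rows[parts[0].upper()] = [float(v) for v in parts[1:]]
        missing = set(ALPHABET) - set(rows)
        if missing:
            raise ValueError(f"index table missing residues {sorted(missing)}")
        raw = np.array([[rows[aa][i] for aa in ALPHABET] for i in range(3)])
        return cls(names=INDEX_NAMES, raw=raw)


# ---------------------------------------------------------------------------
# Encoder configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerConfig:
    k: int = 2

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def dimension(self) -> int:
        return 20**self.k


@dataclass(frozen=True)
class AccConfig:
    lag: int = 14
    index_set: PhysChemIndexSet = field(default_factory=PhysChemIndexSet.default)

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("LAG must be >= 1")

    @property
    def dimension(self) -> int:
        n = self.index_set.n
        return n * n * self.lag


@dataclass(frozen=True)
class PseaacConfig:
    lam: int = 5
    w: float = 0.2
    index_set: PhysChemIndexSet = field(default_factory=PhysChemIndexSet.default)

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")

    @property
    def dimension(self) -> int:
        return 20 + 3 * self.lam


@dataclass(frozen=True)
class FeatureVector:
    scheme: str
    params: object
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")


def _property_signal(seq: ProteinSequence, idx: PhysChemIndexSet) -> np.ndarray:
    """(N, L) matrix of standardized property values; NaN marks sentinels."""
    sig = np.full((idx.n, seq.L), np.nan)
    for j, aa in enumerate(seq.residues):
        if aa != SENTINEL:
            sig[:, j] = idx.normalized[:, AA_TO_INDEX[aa]]
    return sig


# ---------------------------------------------------------------------------
# Kmer
# ---------------------------------------------------------------------------

def kmer_encode(seq: ProteinSequence, cfg: KmerConfig = KmerConfig()) -> FeatureVector:
    """Occurrence frequencies of all 20^k windows of k neighboring residues.

    Windows containing a sentinel residue are skipped and excluded from the
    denominator, so the counted entries still sum to 1.
    """
    k = cfg.k
    if seq.L < k:
        raise SequenceTooShortError(f"sequence {seq.id!r}: L={seq.L} < k={k}")
    codes = np.array([AA_TO_INDEX.get(aa, -1) for aa in seq.residues])
    counts = np.zeros(cfg.dimension)
    n_windows = 0
    for start in range(seq.L - k + 1):
        window = codes[start : start + k]
        if np.any(window < 0):
            continue
        index = 0
        for c in window:
            index = index * 20 + int(c)
        counts[index] += 1
        n_windows += 1
    if n_windows:
        counts /= n_windows
    return FeatureVector(scheme="kmer", params=cfg, values=counts)


def kmer_labels(k: int) -> list[str]:
    """The k-mer string for each component, in output order."""
    labels = [""]
    for _ in range(k):
        labels = [p + aa for p in labels for aa in ALPHABET]
    return labels


# ---------------------------------------------------------------------------
# ACC
# ---------------------------------------------------------------------------

def acc_encode(seq: ProteinSequence, cfg: AccConfig = AccConfig()) -> FeatureVector:
    """Auto-cross covariance vector, lag-major then ordered index pair.

    Component order: for lag = 1..LAG, for (u1, u2) in the fixed index order
    (all N*N ordered pairs), the AC term when u1 == u2 else the CC term.
    """
    idx = cfg.index_set
    n = idx.n
    sig = _property_signal(seq, idx)
    valid = ~np.isnan(sig[0])
    if seq.L <= cfg.lag:
        raise SequenceTooShortError(
            f"sequence {seq.id!r}: L={seq.L} <= LAG={cfg.lag} (lag {cfg.lag} needs L - lag >= 1)"
        )
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise SequenceTooShortError(f"sequence {seq.id!r} has no canonical residues")
    means = np.nansum(sig, axis=1) / n_valid
    centered = sig - means[:, None]
    out = np.empty(cfg.dimension)
    pos = 0
    for lag in range(1, cfg.lag + 1):
        left = centered[:, : seq.L - lag]
        right = centered[:, lag:]
        pair_valid = valid[: seq.L - lag] & valid[lag:]
        n_pairs = int(pair_valid.sum())
        for u1 in range(n):
            for u2 in range(n):
                if n_pairs == 0:
                    out[pos] = 0.0
                else:
                    prod = left[u1, pair_valid] * right[u2, pair_valid]
                    out[pos] = prod.sum() / n_pairs
                pos += 1
    return FeatureVector(scheme="acc", params=cfg, values=out)


def acc_labels(cfg: AccConfig) -> list[str]:
    names = cfg.index_set.names
    labels = []
    for lag in range(1, cfg.lag + 1):
        for u1 in names:
            for u2 in names:
                kind = "AC" if u1 == u2 else "CC"
                labels.append(f"{kind}_{u1}_{u2}_lag{lag}")
    return labels


# ---------------------------------------------------------------------------
# SC-PseAAC
# ---------------------------------------------------------------------------

def tau_factors(
    seq: ProteinSequence, lam: int, idx: PhysChemIndexSet | None = None
) -> np.ndarray:
    """The 3λ tiered sequence-correlation factors (τ1 .. τ_{3λ}).

    Tier d contributes three factors: the means over i of the products of
    standardized hydrophobicity, hydrophilicity and mass at positions i and
    i + d.  Requires λ < L − 1.
    """
    if idx is None:
        idx = PhysChemIndexSet.default()
    if lam >= seq.L - 1:
        raise SequenceTooShortError(
            f"sequence {seq.id!r}: lambda={lam} must satisfy lambda < L - 1 = {seq.L - 1}"
        )
    sig = _property_signal(seq, idx)
    valid = ~np.isnan(sig[0])
    taus = np.empty(3 * lam)
    for d in range(1, lam + 1):
        pair_valid = valid[: seq.L - d] & valid[d:]
        n_pairs = int(pair_valid.sum())
        for u in range(idx.n):
            if n_pairs == 0:
                taus[3 * (d - 1) + u] = 0.0
            else:
                prod = sig[u, : seq.L - d][pair_valid] * sig[u, d:][pair_valid]
                taus[3 * (d - 1) + u] = prod.sum() / n_pairs
    return taus


def sc_pseaac_encode(
    seq: ProteinSequence, cfg: PseaacConfig = PseaacConfig()
) -> FeatureVector:
    """Series-correlation pseudo amino acid composition (20 + 3λ components).

    The first 20 components are amino-acid frequencies and the remaining 3λ
    are the weighted correlation factors, all divided by the common
    normalizer 1 + w·Στ (the frequencies sum to 1).
    """
    taus = tau_factors(seq, cfg.lam, cfg.index_set)
    counts = np.zeros(20)
    for aa in seq.residues:
        if aa != SENTINEL:
            counts[AA_TO_INDEX[aa]] += 1
    total = counts.sum()
    if total == 0:
        raise SequenceTooShortError(f"sequence {seq.id!r} has no canonical residues")
    freqs = counts / total
    denom = 1.0 + cfg.w * taus.sum()
    if denom <= 0.0:
        raise DegenerateEncodingError(
            f"sequence {seq.id!r}: normalizer 1 + w*sum(tau) = {denom:.3g} <= 0"
        )
    values = np.concatenate([freqs, cfg.w * taus]) / denom
    return FeatureVector(scheme="sc-pseaac", params=cfg, values=values)


def pseaac_labels(cfg: PseaacConfig) -> list[str]:
    labels = list(ALPHABET)
    for d in range(1, cfg.lam + 1):
        for name in cfg.index_set.names:
            labels.append(f"tau_{name}_tier{d}")
    return labels


# ---------------------------------------------------------------------------
# Dispatch and bulk encoding
# ---------------------------------------------------------------------------

SCHEMES = ("kmer", "acc", "sc-pseaac")

_ENCODERS = {
    "kmer": (kmer_encode, KmerConfig),
    "acc": (acc_encode, AccConfig),
    "sc-pseaac": (sc_pseaac_encode, PseaacConfig),
}


def encode(seq: ProteinSequence, scheme: str, cfg=None) -> FeatureVector:
    """Encode a single sequence with the named scheme (default parameters
    when ``cfg`` is omitted)."""
    try:
        encoder, cfg_cls = _ENCODERS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}") from None
    return encoder(seq, cfg if cfg is not None else cfg_cls())


def encode_all(
    seqs: Iterable[ProteinSequence], scheme: str, cfg=None
) -> dict[str, np.ndarray]:
    """Encode many sequences; returns id -> value vector."""
    return {s.id: encode(s, scheme, cfg).values for s in seqs}


def feature_labels(scheme: str, cfg=None) -> list[str]:
    _, cfg_cls = _ENCODERS[scheme]
    cfg = cfg if cfg is not None else cfg_cls()
    if scheme == "kmer":
        return kmer_labels(cfg.k)
    if scheme == "acc":
        return acc_labels(cfg)
    return pseaac_labels(cfg)


def write_feature_tsv(
    vectors: Mapping[str, np.ndarray], scheme: str, cfg, path: str | Path
) -> None:
    labels = feature_labels(scheme, cfg)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(labels) + "\n")
        for sid, vec in vectors.items():
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in vec) + "\n")


def write_svmlight(
    vectors: Mapping[str, np.ndarray], labels: Mapping[str, int], path: str | Path
) -> None:
    """SVM-light sparse format (+1/-1 labels, 1-based feature indices)."""
    with open(path, "w") as fh:
        for sid, vec in vectors.items():
            y = labels[sid]
            feats = " ".join(
                f"{i + 1}:{v:.10g}" for i, v in enumerate(vec) if v != 0.0
            )
            fh.write(f"{y:+d} {feats} # {sid}\n")
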