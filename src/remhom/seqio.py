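"""Sequence and frequency-profile I/O.

A protein is a string over the 20 canonical amino acids in the fixed order
``ACDEFGHIKLMNPQRSTVWY``; this order is used for every index into profile
rows and feature vectors throughout the package.

A frequency profile is a 20 x L column-stochastic matrix: column *j* is the
distribution of amino acids observed at position *j* of the protein during
evolution (typically derived from a PSI-BLAST search).  The profile-based
*pseudo-sequence* takes, at each position, the amino acid with the highest
frequency; downstream sequence encoders then run on that representation
unchanged, so evolutionary information enters without changing the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical amino-acid alphabet in the fixed order used for all indexing.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Sentinel residue for ambiguity codes with no usable substitute; encoders
#: never let a counting window or correlation pair span a sentinel.
SENTINEL = "X"

# Ambiguity-code handling: B/Z/J/U/O have a natural canonical stand-in;
# X and * carry no residue information and become the sentinel.
_SUBSTITUTIONS = str.maketrans(
    {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K", "X": SENTINEL, "*": SENTINEL}
)

_VALID = set(ALPHABET) | {SENTINEL}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def sanitize_residues(raw: str) -> str:
    """Uppercase, strip whitespace and map ambiguity codes onto the alphabet."""
    s = "".join(raw.split()).upper().translate(_SUBSTITUTIONS)
    bad = set(s) - _VALID
    if bad:
        raise FormatError(f"unknown residue code(s) {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the canonical alphabet (plus sentinel)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be nonempty")
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise FormatError(f"sequence {self.id!r} has invalid residues {sorted(bad)!r}")

    @property
    def L(self) -> int:
        return len(self.residues)


@dataclass
class FrequencyProfile:
    """Per-position amino-acid distribution: 20 rows (canonical order) x L columns.

    Every column sums to 1; loaders renormalize to enforce this.
    """

    seq_id: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 20:
            raise ValueError(f"profile matrix must be 20 x L, got {self.matrix.shape}")
        if self.matrix.shape[1] < 1:
            raise ValueError("profile must cover at least one position")
        if np.any(self.matrix < 0):
            raise ValueError("profile frequencies must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("profile columns must sum to 1 (renormalize on load)")

    @property
    def L(self) -> int:
        return int(self.matrix.shape[1])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly empty) multi-record FASTA file.

    Residues are sanitized (see :func:`sanitize_residues`); record order is
    preserved.  An empty sequence or unparseable record raises
    :class:`FormatError` naming the offending record.
    """
    out: list[ProteinSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record #{len(out) + 1} has a malformed header")
        residues = sanitize_residues(str(rec.seq))
        if not residues:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM (-out_ascii_pssm layout)
# ---------------------------------------------------------------------------

def read_ascii_pssm(path: str | Path) -> FrequencyProfile:
    """Read a PSI-BLAST ASCII PSSM and return its frequency profile.

    Only the 20 weighted-percentage columns are used (they approximate the
    per-position target frequencies).  Each position's percentages are divided
    by 100 and renormalized to sum to 1; a position whose 20 percentages are
    all zero (PSI-BLAST emits these for positions without alignment coverage)
    falls back to a one-hot column at the query residue.

    The layout is: header lines, then one row per position holding the
    position index, the query residue, 20 log-odds integers, 20
    weighted-percentage integers, and trailing information-content columns.
    """
    path = Path(path)
    columns: list[np.ndarray] = []
    header_order: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            # The double header line lists the 20-letter column order twice.
            if header_order is None and len(tokens) >= 40 and all(t in _VALID for t in tokens[:40]):
                header_order = tokens[20:40]
                continue
            if not tokens[0].isdigit():
                continue  # header / footer lines (Lambda, K, comments)
            if len(tokens) < 42:
                raise FormatError(f"{path}:{lineno}: expected >=42 columns, got {len(tokens)}")
            query_res = sanitize_residues(tokens[1])
            try:
                pct = np.array([float(t) for t in tokens[22:42]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric percentage field") from exc
            if header_order is not None:
                # reorder from the file's column order into canonical order
                reordered = np.empty(20)
                for src, aa in enumerate(header_order):
                    reordered[AA_TO_INDEX[aa]] = pct[src]
                pct = reordered
            total = pct.sum()
            if total <= 0:
                col = np.zeros(20)
                col[AA_TO_INDEX[query_res]] = 1.0
            else:
                col = pct / total
            columns.append(col)
    if not columns:
        raise FormatError(f"{path}: no position rows found")
    return FrequencyProfile(seq_id=path.stem, matrix=np.column_stack(columns))


# ---------------------------------------------------------------------------
# Profile TSV (seq_id, position, 20 frequency columns)
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: FrequencyProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\t" + "\t".join(ALPHABET) + "\n")
        for j in range(profile.L):
            vals = "\t".join(f"{v:.10g}" for v in profile.matrix[:, j])
            fh.write(f"{profile.seq_id}\t{j + 1}\t{vals}\n")


def read_profile_tsv(path: str | Path) -> FrequencyProfile:
    path = Path(path)
    seq_id = None
    columns = []
    with open(path) as fh:
        header = fh.readline().split("\t")
        if len(header) != 22:
            raise FormatError(f"{path}: expected 22 tab-separated header fields")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 22:
                raise FormatError(f"{path}:{lineno}: expected 22 fields, got {len(parts)}")
            seq_id = parts[0]
            try:
                col = np.array([float(v) for v in parts[2:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric frequency") from exc
            total = col.sum()
            if total <= 0:
                raise FormatError(f"{path}:{lineno}: column sums to zero")
            columns.append(col / total)
    if seq_id is None:
        raise FormatError(f"{path}: no profile rows")
    return FrequencyProfile(seq_id=seq_id, matrix=np.column_stack(columns))


# ---------------------------------------------------------------------------
# Pseudo-sequences
# ---------------------------------------------------------------------------

def profile_to_pseudo_sequence(profile: FrequencyProfile) -> ProteinSequence:
    """Most-frequent residue per column; ties break to the first residue in
    canonical alphabet order."""
    idx = np.argmax(profile.matrix, axis=0)  # argmax takes the first maximum
    residues = "".join(ALPHABET[i] for i in idx)
    return ProteinSequence(id=profile.seq_id, residues=residues)


def one_hot_profile(seq: ProteinSequence) -> FrequencyProfile:
    """The degenerate profile that puts all mass on the observed residue.

    Sentinel positions get a uniform column (no residue information).
    """
    m = np.zeros((20, seq.L))
    for j, aa in enumerate(seq.residues):
        if aa == SENTINEL:
            m[:, j] = 1.0 / 20.0
        else:
            m[AA_TO_INDEX[aa], j] = 1.0
    return FrequencyProfile(seq_id=seq.id, matrix=m)
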