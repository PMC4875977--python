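# Methods

## Problem and model

Remote homologs share a structural superfamily but have diverged beyond the
reach of pairwise alignment. `remhom` treats detection as a per-superfamily
binary ranking problem: for each held-out *family*, an SVM is trained with
the family's sibling families (same superfamily) as positives and sequences
from unrelated folds as negatives, then asked to rank the held-out family's
members above unrelated test negatives. Repeating this over every family and
averaging per-family ROC / ROC50 gives the benchmark score.

Three fixed-length encoders supply complementary views of a sequence:
composition (Kmer), physicochemical sequence order (ACC), and a joint
composition + order representation (SC-PseAAC). One RBF-kernel SVM is
trained per (encoder, family task); the per-task ensemble score is the
weighted sum of the three classifiers' normalized decision values, the
weight of each classifier being its average ROC score for that task.

## Encoders: definitions and numerical choices

All indexing uses the fixed residue order `ACDEFGHIKLMNPQRSTVWY`.

**Kmer** (dim 20^k, default k = 2). Frequencies of all k-residue windows,
normalized by the number of *counted* windows. Windows that span a sentinel
residue (`X`, from ambiguity codes with no canonical substitute) are skipped
and removed from the denominator, so the vector still sums to 1. Ambiguity
codes with a natural stand-in are substituted on input (B→D, Z→E, J→L, U→C,
O→K); only X and `*` become sentinels.

**ACC** (dim N²·LAG; 126 at the defaults N = 3, LAG = 14). For standardized
property signals P_u along the sequence,

    AC(u, d)      = Σ_{i=1..L−d} (P_u(R_i) − P̄_u)(P_u(R_{i+d}) − P̄_u) / (L − d)
    CC(u1, u2, d) = Σ_{i=1..L−d} (P_u1(R_i) − P̄_u1)(P_u2(R_{i+d}) − P̄_u2) / (L − d)

with P̄_u the per-sequence mean. Component order is lag-major, then the
N × N ordered index pairs — the order is arbitrary (SVMs are insensitive to
it) but fixed so files reproduce byte-identically. With sentinels present,
pairs spanning a sentinel are excluded and denominators are the count of
valid pairs; property means are taken over canonical residues. Requires
L > LAG.

**SC-PseAAC** (dim 20 + 3λ; 35 at λ = 5, w = 0.2). Amino-acid frequencies
f_u plus 3λ tiered correlation factors; tier d holds the means over i of
ĥ1(R_i)ĥ1(R_{i+d}), ĥ2(R_i)ĥ2(R_{i+d}), m̂(R_i)m̂(R_{i+d}), each summed over
the L − d valid positions and divided by (L − d). The whole vector is
divided by 1 + w·Στ (the frequencies sum to 1). Defined only for
λ < L − 1; a normalizer ≤ 0 (possible when w·Στ ≤ −1) raises a
degenerate-encoding error rather than returning a sign-flipped vector.

**Physicochemical indices.** Hydrophobicity, hydrophilicity (Hopp–Woods) and
side-chain mass, the canonical triple used with pseudo amino acid
composition, shipped in `features.py` and overridable via a 20-row TSV. All
three are standardized to zero mean and unit *population* variance over the
20 residues (divide by the root mean squared deviation, not the n−1 sample
SD). ACC also uses the standardized values: standardization makes the three
indices commensurable, and covariances of shifted/scaled signals differ only
by a constant factor per component, which the SVM absorbs.

## Profiles and pseudo-sequences

A frequency profile is a 20 × L column-stochastic matrix. The ASCII PSSM
reader uses only the 20 weighted-percentage columns (an approximation of the
target frequencies), divides by 100 and renormalizes each column;
orphan positions whose percentages are all zero fall back to a one-hot
column at the query residue. The pseudo-sequence takes the argmax residue
per column; ties break to the first residue in canonical order, making the
mapping deterministic. Synthetic profiles are per-column Dirichlet draws
with parameter `concentration` on the true residue and 0.5 elsewhere:
concentration → ∞ recovers the sequence exactly, concentration ≈ 10 yields
~99 % positional identity (the contract tested is ≥ 90 %).

## Classifiers and ensemble

SVMs are scikit-learn `SVC` with RBF kernel and pinned defaults C = 1,
gamma = 1/(n_features · Var(X)) ("scale"). No class reweighting by default
(`class_weight="balanced"` is available). Raw decision values are min-max
normalized per classifier using the *training pool's* score range, clipped
to [0, 1]; degenerate ranges map everything to 0.5. Normalization is
monotone, so per-classifier ROC is unchanged; its purpose is to put the
three classifiers' belief values on a common scale before voting.

Ensemble weights are the classifiers' average ROC estimated by stratified
3-fold CV on training data (shuffled with the run seed; deterministic given
the seed). Estimating weights on the test set would leak labels; the
literal variant is retained as `weights_from="oracle"` for comparison only.
Weights are applied raw, not renormalized — they are ROC scores and the
argmax over superfamilies is scale-sensitive only through them.
Superfamily assignment is the argmax of ensemble scores; ties break to the
lexicographically smallest superfamily id.

## Metrics

ROC is computed as the Mann–Whitney statistic (ties ½) via average ranks —
identical to trapezoidal AUC with tie interpolation. ROC50 truncates the
ranked list at the 50th false positive and normalizes by
n_pos × min(50, n_neg), so it lies in [0, 1] and reduces exactly to ROC when
n_neg ≤ 50. At equal scores the ROC50 curve places negatives first
(pessimistic): the truncated metric is the headline early-retrieval number
and should not be inflated by tie luck. Family averages are unweighted.

## Synthetic benchmark: what it emulates, and what it does not

The generator reproduces the *structure* of superfamily hold-out
benchmarks: per superfamily, an ancestral sequence with implanted motifs;
families as mutated descendants (between-family rate 0.65, within-family
rate 0.30 substitutions/site); superfamily-specific composition only mildly
biased (Dirichlet concentration 400 around the shared background), so
detection rests on motifs and residual ancestry rather than trivial
composition shifts. Half of all substitutions are class-conserving (drawn
from the same hydrophobic / polar / charged class), so physicochemical
autocorrelation outlives exact k-mer content — giving the covariance
encoders signal partially complementary to Kmer, as real superfamilies do.
Defaults (6 superfamilies × 3 families × 20 sequences × 120 residues) were
chosen so that single-scheme mean ROC lands in the 0.8–0.95 band reported
for real remote-homology benchmarks with the composition encoder strongest,
and so that a full multi-seed pipeline run completes in minutes on one CPU;
every family task has 40 training and 20 test positives (floor: 10 / 5).

Mutations are i.i.d. substitutions; indels are off by default (`indel_rate`
exists) since all encoders are length-free. The generator does **not**
emulate phylogenetic correlation along a tree, alignment-based profile
construction, domain architecture, or database search noise — passing tests
show the pipeline's correctness and the ensemble's qualitative behaviour,
not absolute performance on SCOP-derived data.

## Limitations

- Absolute benchmark numbers from profile-based studies are out of reach
  without the original sequence set and NR-derived profiles; all quantitative
  checks here are analytic anchors, oracle equivalences, and qualitative
  ordering on synthetic data.
- Whether weighted PSSM percentages equal the target frequencies used by
  profile-based methods is approximate at best; the reader renormalizes and
  documents the choice.
- CV-estimated weights are a proxy for the stated "average ROC on the
  superfamily"; with few training positives they are noisy, which slightly
  blunts the ensemble's edge on small tasks.
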