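# remhom

Protein **remote homology detection**: deciding whether a query protein
belongs to a structural superfamily when its sequence identity to every known
member is too low (≲ 35 %) for alignment-based search. `remhom` implements a
discriminative approach for this setting: per-superfamily support vector
machines trained on three complementary fixed-length sequence encodings,
combined by ROC-weighted voting, and evaluated with the ROC / ROC50 ranking
metrics standard in this literature. It is intended for bioinformaticians who
want a self-contained, testable implementation of the ensemble pipeline — from
FASTA (or PSI-BLAST profile) input to per-family benchmark tables.

## The method

**Profile-based pseudo-sequences.** A frequency profile 𝕄 is a 20 × L
column-stochastic matrix: m_{i,j} is the probability of amino acid i at
position j (from a PSI-BLAST search; `remhom` parses the ASCII PSSM layout but
does not run PSI-BLAST). Taking the most frequent residue per column yields a
*pseudo-sequence* that carries evolutionary information yet can be fed to any
sequence encoder.

**Three encoders** map a sequence P = R₁R₂…R_L to a fixed-length vector:

- *Kmer* (dim 20^k, default k = 2): occurrence frequencies of all k-residue
  windows.
- *ACC* (dim N²·LAG = 126 at N = 3, LAG = 14): lagged auto/cross covariances
  of standardized hydrophobicity, hydrophilicity and side-chain mass signals,
  AC(u, d) = Σᵢ (P_u(Rᵢ) − P̄_u)(P_u(R_{i+d}) − P̄_u) / (L − d), and the
  analogous CC(u₁, u₂, d) for u₁ ≠ u₂.
- *SC-PseAAC* (dim 20 + 3λ = 35 at λ = 5, w = 0.2): amino-acid frequencies
  f_u plus 3λ tiered correlation factors τ_j, jointly normalized as
  x_u = f_u / (Σf + wΣτ) and x_{20+j} = wτ_j / (Σf + wΣτ).

**Ensemble.** For each superfamily S_j, one RBF-kernel SVM per encoder is
trained (positives: sibling families of the held-out family; negatives: other
folds). Decision values are min-max normalized to [0, 1] per classifier, and
combined as C_{S_j}(P) = Σᵢ w_{iS_j} · C_{iS_j}(P, S_j), where the weight
w_{iS_j} is classifier i's average ROC score on S_j, estimated by stratified
3-fold cross-validation on training data. A query is assigned to the
superfamily with the highest ensemble score.

**Metrics.** ROC score = Mann–Whitney statistic (1 = perfect ranking, 0.5 =
random); ROC50 = area under the ROC curve up to the 50th false positive,
normalized to [0, 1].

Because the real superfamily benchmark requires a SCOP-derived sequence set
plus PSI-BLAST profiles against NR, the package ships a seeded **synthetic
superfamily generator** with the same train/test structure (held-out family
as test positives, siblings as training positives, other superfamilies as
negatives, ≥ 10 training / ≥ 5 test positives per family) so the full
pipeline runs and is tested at desk scale.

## Worked example

```python
import remhom as rh
from remhom.evaluate import collect_task_scores, tabulate

cfg = rh.SynthConfig(seed=1)                  # 6 superfamilies x 3 families x 20 seqs
seqs, split = rh.generate_benchmark(cfg)
vectors = {s: rh.encode_all(seqs, s) for s in rh.SCHEMES}
records = collect_task_scores(rh.tasks_from_split(split), vectors, folds=3, seed=1)
for combo in [("kmer",), ("acc",), ("sc-pseaac",), rh.SCHEMES]:
    t = tabulate(records, combo)
    print(" + ".join(combo), f"mean ROC {t.roc.mean():.3f}  mean ROC50 {t.roc50.mean():.3f}")
```

prints

```
kmer mean ROC 0.949  mean ROC50 0.855
acc mean ROC 0.863  mean ROC50 0.659
sc-pseaac mean ROC 0.916  mean ROC50 0.778
kmer + acc + sc-pseaac mean ROC 0.967  mean ROC50 0.904
```

Each mean is the unweighted average over the 18 held-out family tasks of the
per-family ROC / ROC50. The composition encoder is the strongest single
scheme, the covariance encoder the weakest, and the weighted ensemble beats
every single scheme — the qualitative behaviour that motivates combining
complementary feature spaces.

The same pipeline is available from the shell:

```bash
remhom simulate --seed 1 --out bench/
remhom benchmark --split bench/splits.tsv --fasta bench/sequences.fasta \
    --ensemble --seed 1 --report report.tsv
remhom grid-search --split bench/splits.tsv --fasta bench/sequences.fasta \
    --scheme kmer --grid '[{"k": 1}, {"k": 2}]' --report grid.tsv
```

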