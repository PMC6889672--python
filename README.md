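# irfmda

Random-forest scoring of candidate microRNA–disease associations.

Dysregulated miRNAs are implicated in many human diseases, but confirming an
association experimentally is slow and expensive, so curated databases cover
only a sparse corner of the disease × miRNA grid. `irfmda` is a tool for
prioritizing the unconfirmed cells of that grid: given a table of
experiment-supported associations, per-disease ontology ancestor DAGs, and an
optional precomputed miRNA functional-similarity matrix, it assigns every
unconfirmed (disease, miRNA) pair a score in [0, 1], with higher scores
indicating a more plausible association. It is aimed at computational
biologists who want a ranked candidate list to guide experiments, and at
methodologists who want a transparent, testable reference implementation of
this family of similarity-plus-forest link predictors.

## Method

Let *DMAM* be the binary nd × nm association matrix. Four similarity sources
are computed and merged:

- **Disease semantic similarity** (two models) from ontology DAGs. Model 1
  gives each DAG vertex a contribution toward disease *D* of
  CS1_D(D) = 1 and CS1_D(d) = Δ · max{CS1_D(d′) : d′ a child of d}
  (Δ = 0.5); model 2 uses the frequency-based contribution
  CS2(d) = −log(#DAGs containing d / #diseases). Either way

      DSS(di, dj) = Σ_{d ∈ S(di) ∩ S(dj)} (CS_di(d) + CS_dj(d)) / (DS(di) + DS(dj)),

  where S(D) is the vertex set of DAG(D) and DS(D) the total contribution.
- **Gaussian interaction-profile kernel (GIPK)** similarity on both axes:
  K(i, j) = exp(−α‖IP(i) − IP(j)‖²) with IP(·) a row/column of *DMAM* and
  α = α′ / mean‖IP‖² (α′ = 1).
- **Integration**: disease similarity is the mean of the two semantic models
  when both diseases have DAGs, else the kernel; miRNA similarity is the
  precomputed functional score when both miRNAs are covered, else the kernel.

A pair (d, m) is represented by the concatenation of m's integrated-similarity
row and d's integrated-similarity row (878 dimensions at the scale of the
HMDD v2.0 snapshot: 495 + 383), min–max normalized per feature. Training
pairs are the known positives plus an equal number of unconfirmed pairs
sampled uniformly as negatives. Features are ranked by out-of-bag
permutation variable importance,

    S_j = (1/B) Σ_b (R_b^oob − R_bj^oob),

the mean drop in OOB accuracy after permuting feature j (averaged over
resampled runs), and the top-k (default 100) are kept. A regression forest
(ntree = 500, mtry = ⌊k/3⌋) fitted on the 0/1 labels scores all unconfirmed
pairs. Validation is ranking-based: global/local leave-one-out and repeated
5-fold cross-validation with Mann–Whitney AUC over held-out ranks.

## Worked example

Everything runs on self-generated synthetic data; no downloads are needed.

```
$ irfmda simulate --nd 20 --nm 30 --groups 2 --p-in 0.5 --p-out 0.03 --seed 7 --out world
wrote planted world (159 associations) to world

$ cat > config.yaml <<EOF
importance_ntree: 100
importance_folds: 3
k: 20
rf_ntree: 200
EOF

$ irfmda run-all --config config.yaml \
    --associations world/associations.tsv --dags world/dags.tsv \
    --functional world/similarity.tsv --seed 7 --out results
pipeline complete; artifacts in results

$ head -4 results/predictions.tsv
disease	mirna	score
disease_000	mirna_000	0.8245544922
disease_000	mirna_001	0.8112834789
disease_000	mirna_002	0.8022614391
```

The simulated world has two latent groups of diseases and miRNAs with dense
within-group association probability (0.5) and sparse cross-group probability
(0.03); `predictions.tsv` lists every unconfirmed pair, sorted within each
disease by descending score, and the top-ranked partners of `disease_000`
are (correctly) miRNAs from its own group. `results/` also contains the six
similarity matrices, the labeled dataset, the importance table, the fitted
model and a manifest with every seed and parameter.

Ranking-based validation of the same inputs:

```
$ irfmda evaluate --config config.yaml \
    --associations world/associations.tsv --dags world/dags.tsv \
    --functional world/similarity.tsv --protocol kfold --folds 5 --seed 7 --out eval
{"auc_mean_of_repeats": 0.8106, "auc_pooled": 0.8106, "n_repeats": 1, "n_test": 159, "protocol": "kfold", "seed": 7}
```

Each of the 159 known associations was held out in a fold, similarities and
the model were rebuilt from the remaining data (strict no-leakage policy),
and the held-out pair was ranked against all unconfirmed pairs; an AUC of
0.81 means a held-out true association outranks a random unconfirmed pair
81% of the time.

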