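# Methods

## Model and assumptions

`irfmda` treats miRNA–disease association prediction as positive-unlabeled
bipartite link prediction under the standard guilt-by-association premise:
functionally similar miRNAs tend to associate with phenotypically similar
diseases. The curated association table supplies the positives; everything
unconfirmed is treated as unlabeled, and a balanced training set labels a
uniform random sample of unconfirmed pairs 0. This is an approximation —
some sampled "negatives" are undiscovered positives — and is the main
statistical caveat of the whole model family.

The pair representation assumes the integrated similarity row of an entity
is an adequate summary of that entity: the feature vector of (d, m) is row m
of the integrated miRNA similarity matrix followed by row d of the
integrated disease similarity matrix. Nothing about the specific cell (d, m)
enters the vector except through the similarity matrices.

## Similarity components

**Semantic similarity** needs one ancestor DAG per disease, supplied as a
pre-extracted edge list (`disease<TAB>child<TAB>parent`; ontology-XML
parsing is out of scope). Model 1 decays contributions by Δ per layer,
taking the max over in-DAG children for multi-path ancestors; Δ = 0.5,
configurable, following the convention of this literature. Model 2 scores a
vertex by −log of the fraction of DAGs containing it, computed over the DAG
collection actually supplied (the natural choice of universe; the log base
cancels in the similarity ratio, so natural log is used). If two diseases
both have semantic value 0 — possible in model 2 when every vertex is
ubiquitous — their similarity is defined as 1 on the diagonal and 0 off it,
preserving self-similarity without inventing signal.

**GIPK similarity** is an RBF kernel on binary interaction profiles with the
bandwidth normalized by the mean squared profile norm (raw bandwidth α′ = 1
on both axes). An individual all-zero profile is allowed — a disease
stripped of its associations in a hold-out still needs a kernel row — and
two all-zero profiles have similarity 1; only a fully zero profile set is an
error.

**Integration** is entrywise and pairwise-masked: the semantic mean where
both diseases have DAGs, the functional score where both miRNAs are covered,
the kernel otherwise. Coverage is derived from DAG presence and from the
labels of the functional matrix.

## Dataset, selection, forest

Min–max normalization is per feature column over the training samples;
constant columns map to 0; prediction-time rows reuse the stored training
statistics and are clipped to [0, 1]. (Normalizing before or after feature
selection yields identical selected-column values under per-column min–max;
the full matrix is normalized first.)

Permutation importance is computed on a forest built tree-by-tree from
explicit bootstrap draws, because the definition needs each tree's exact
out-of-bag membership. Per tree: OOB predictions are thresholded at 0.5
against the 0/1 labels to give an accuracy; each feature column is permuted
once within the OOB rows (features the tree never splits on are skipped —
their permutation cannot change predictions); the importance of a feature
is the mean accuracy drop over trees. Trees with an empty OOB set are
skipped. Scores are averaged over 10 resampled runs by default, each run
seeing one training partition of a 10-fold split of the samples; this
interpretation of "averaged over 10 folds" is one of several defensible
readings and is configurable (`importance_folds=1` gives a single full-data
run). An MSE-increase variant is available behind `criterion="mse"` for
users who prefer a regression-native score; the accuracy form is the
default because the labels are binary. Ranking is descending with stable
ties (original feature order).

The scorer is a regression forest on 0/1 targets: ntree = 500,
mtry = ⌊features/3⌋, terminal node size 5 — the regression defaults of the
classical randomForest implementation — with predictions clipped to [0, 1].
Seeds: one pipeline seed fans out with fixed offsets to negative sampling,
importance, and the forest, so every artifact is reproducible from the
manifest.

## Evaluation protocols and the leakage policy

Held-out positives are ranked (descending score, mean rank for ties)
against the unlabeled pairs — all of them for global LOOCV and k-fold CV,
those of the test disease for local LOOCV. The protocol AUC is the mean of
(n + 1 − rank)/n over held-out positives, which equals the Mann–Whitney
probability that a held-out positive outranks a random unlabeled pair; the
ROC module computes the same statistic from a threshold sweep with ties
counted half. Repeated k-fold results are summarized both as the mean of
per-repeat AUCs and as the AUC of the pooled ranks, labeled accordingly.

Two leakage policies are exposed because the choice materially affects AUC.
**strict** (default): for every hold-out, the similarities, features,
normalization, feature selection and forest are rebuilt from the
training-only association matrix, so no information about a test pair
reaches the model. **paper-fast**: similarities, features and selection are
built once from all data and only the forest is retrained per hold-out —
the cheaper reading common in this literature, and mildly optimistic,
because kernel profiles then already contain every test association.
Full per-positive LOOCV retraining is O(#positives) pipeline fits; a
`grouped_loocv` flag shares one fit across all positives of a disease as a
desk-scale approximation and is labeled as such.

## The synthetic planted world

The generator emulates the statistical structure the predictor assumes:
diseases and miRNAs fall into latent groups (defaults nd = 40, nm = 60,
4 groups); associations are Bernoulli with within-group probability
p_in = 0.35 and cross-group p_out = 0.02; same-group diseases share an
ancestor chain (one chain per group under a global root), making model-1
semantic similarity block-informative with hand-checkable values; the
functional matrix is uniform noise plus a within-group boost, symmetrized,
unit diagonal. The functional matrix covers every miRNA (as the real
precomputed resource does) while 10% of diseases lack a DAG (as real
ontology coverage does), which keeps the kernel branch of the integration
rule live end to end.

What the world does **not** emulate: deep multi-parent ontology
hierarchies, heavy-tailed association degrees, soft group structure, and
biased (non-uniform) negative discovery. Passing the end-to-end benchmark
therefore demonstrates that the machinery recovers planted block signal
reproducibly — not that any particular real-data AUC is attainable.

### Why strict-leakage AUC on the planted world is bounded

In a Bernoulli block world, a held-out positive is statistically
exchangeable with the unconfirmed cells of the same block: no scorer built
without the test cell can separate them beyond realized-degree noise. The
resulting ceiling — the AUC of an oracle that scores by the true block
indicator — is about 0.84 under the default parameters (and adding realized
degree information moves it by < 0.01). The pipeline itself measures
≈ 0.69–0.77 across generator seeds under the strict policy and ≈ 0.80 under
paper-fast with the default benchmark settings (5-fold, importance 100 trees × 3 runs, top-50 of 100
features, 500-tree scorer; sizes chosen to keep the benchmark at minutes
scale). The strict-mode gap below the ceiling is itself informative: kernel
features computed from the training matrix encode cell-presence
fingerprints that the forest exploits in training but that do not survive a
strict hold-out, exactly the effect the strict policy exists to expose. The
matched null world (p_in = p_out) scores ≈ 0.50, confirming the pipeline
invents no signal.

## Numerical choices and degenerate inputs

- Similarity matrices are validated symmetric (1e-8 on file input, 1e-12 in
  memory), non-negative; model-1 semantic and kernel diagonals are set to
  exactly 1. Files are TSV, 10 significant digits, which re-reads to within
  1e-9 relative and is byte-stable on rewrite.
- Name matching is case-sensitive after whitespace trimming: silent folding
  would hide curation errors.
- Negative sampling is rejection sampling without replacement from the zero
  cells; drawing more negatives than zero cells is an error.
- Ties in feature ranking break by original feature order; ties in
  candidate ranking get the mean rank (unbiased AUC).
- Degenerate feature columns (max = min) normalize to 0. Single-class
  training sets, empty DAG collections, all-zero profile sets, cyclic DAGs
  and vertices with no path to their disease are errors, reported with the
  offending entity.

## Known limitations

- Random negatives contaminated by undiscovered positives bias scores
  downward for the most promising candidates.
- The importance score with one permutation per (tree, feature) is noisy
  for weak features; `importance_repeats` reduces the variance at linear
  cost.
- Strict LOOCV at real-data scale (thousands of pipeline refits) is
  computationally heavy by design; the grouped approximation and the
  paper-fast policy are the documented trade-offs.
- Scoring every pair materializes an (nd·nm) × k feature matrix; at very
  large scales this should be chunked.
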