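# Methods

## The model

`pertbarcode` learns a compact binary representation ("perturbation
barcode") of L1000-style gene expression profiles.  The input to the model
is a 978-element vector of robust z-scores: for each landmark gene, a
sample's plate-normalised expression standardised against the median and
median absolute deviation (MAD) of the 12–16 vehicle (DMSO) control wells on
its plate,

    z[g, s] = (x[g, s] − median_vehicle[g]) / (MAD_vehicle[g] · k).

The MAD consistency constant k = 1.4826 (which makes the MAD estimate the
standard deviation under normality) is applied by default and can be turned
off for bit-compatibility with pipelines that use the raw MAD.  A zero
vehicle MAD is an error, never silently inflated: a z-score against a
degenerate scale estimate is meaningless.

The encoder is a siamese multilayer perceptron.  Two profiles enter as
adjacent rows and pass through shared weights: two hidden layers of 400 and
100 sigmoid units whose pre-activations receive independent Gaussian noise
of variance 0.25 during training ("noisy sigmoid").  The squared Euclidean
distance d² between the two 100-unit representations feeds a rectified
margin cost

    c = softplus(1 − y·(m − d²)),   softplus(x) = ln(1 + eˣ),

with label y = +1 for biological replicates, −1 otherwise, and margin m = 5
in squared-distance units.  Replicate pairs are penalised as d² exceeds the
margin, non-replicate pairs as d² falls below it; the softplus makes the
hinge smooth and total.  Training minimises the mean pair cost plus an L1
penalty (λ = 10⁻⁶ by default, 10⁻⁶–10⁻⁵ is the sensible range) on the
weight matrices — not the biases — by minibatch RMSprop (learning rate
10⁻³, decay 0.9, ε = 10⁻⁸), with dropout p = 0.5 on both hidden-layer
outputs, inverted scaling so inference needs no rescaling.  Weights are
initialised uniformly at ±1/√fan-in; everything is seeded.

Inference is deterministic: no noise, no dropout.  The pre-activation noise
drives hidden activations towards saturation, so the trained second hidden
layer is almost binary; thresholding it at 0.5 (values ≥ 0.5 → 1) yields
the 100-bit barcode.  A replicate group's consensus barcode averages the
raw activations across replicates before thresholding.

### Design choices that were genuinely open

- **Dropout is shared within a pair.**  The two pair members pass through
  the *same* thinned network: one dropout mask is drawn per pair and
  applied to both rows.  With independent masks, mask mismatch alone gives
  a replicate pair an expected squared distance of about 2 per active unit
  — far above the margin of 5 — and training collapses to predicting every
  pair a replicate (we observed exactly this).  Sharing the mask is the
  coherent reading of siamese weight sharing.  Pre-activation noise, by
  contrast, *is* drawn independently per row and per unit.
- **Noise before dropout.**  Noise is injected into the pre-activation;
  dropout applies to the post-sigmoid output.
- **Classification rule.**  Pair-level accuracy uses the cost's
  indifference surface: predict replicate iff d² < m, ties (d² = m)
  classified non-replicate.  The rule and threshold are configurable.
- **Output width vs margin.**  A sigmoid layer of width w bounds d² by w,
  so the second hidden layer must be wider than the margin or
  non-replicates can never cross it.  The default (100 units, m = 5) is
  comfortably safe; tiny test models use ≥ 16 units.
- **Best-validation checkpointing.**  Per-epoch mean training cost and
  validation pair accuracy are recorded; the returned weights are those of
  the best validation epoch.

## Pair construction

Splits are made at the compound level (80/10/10 by default) so all
replicates of a compound fall in one partition.  Positives are sampled
uniformly without replacement from within-replicate-group pairs (up to
40 000 by default); negatives pair samples of *different* compounds at a
2:1 negative:positive ratio, so replicate pairs are one third of the
stream.  Negatives deliberately exclude same-compound pairs in different
replicate groups (e.g. other doses): "non-replicate" here means "different
treatment".  Pair sampling, splitting and minibatch shuffling are all
reproducible from seeds.

## Baselines

- **Random predictor** matched to the replicate frequency q: accuracy
  q² + (1−q)², precision = recall = F1 = q.  At the 1:2 sampling ratio
  (q = 1/3) this gives 55.6% accuracy and F1 = 0.33.
- **Thresholding** of the z-scores (shared or per-gene threshold, signed or
  absolute scale) with thresholds learned by gradient descent on a
  sigmoid-relaxed binarisation (temperature 0.5) under the same margin
  cost.
- **Random sign projections** (LSH-style): h = Pᵀz with P ~ N(0,1), bit = 1
  iff h ≥ 0.
- **Learned linear projections** (k = 100): the same margin cost and
  optimiser as the network, i.e. the linear ablation of the model.
- **GSEA profiles**: per gene set, a two-sample Wilcoxon rank-sum test of
  in-set versus out-of-set z-scores within a sample, scored as the
  tie-corrected, continuity-corrected normal-approximation z statistic
  (midranks for ties; sign positive when in-set genes rank higher).  The
  continuity correction shrinks |z| by 0.5/σ, the standard two-sided
  convention.

## Evaluation battery

All metrics operate on Euclidean distance matrices of a representation
(barcode bits are 0/1 vectors, so their Euclidean distance is the square
root of the Hamming distance).

- **Median replicate rank.**  For each sample with a replicate, all samples
  are ranked by ascending distance, the query pinned at rank 1; the rank of
  the nearest replicate is recorded and the median over queries reported.
  Ties get average ranks — important for barcodes, whose discrete distances
  tie often.  Best attainable value: 2.
- **Shared-target t.**  Per-compound consensus representations; compounds
  with at least one sub-micromolar (< 1 µM) target enter.  Welch's t (by
  default) contrasts distances of target-sharing vs non-sharing pairs;
  negative = sharing pairs closer.  A per-target variant averages
  one-vs-rest t statistics over targets.  All pairs are used (no
  subsampling cap by default).
- **Clustering overlap.**  Average-linkage hierarchical clustering with the
  dendrogram cut at the height maximising the silhouette score — a
  deterministic simplification of adaptive tree cutting — with clusters
  below the minimum size (3) merged into the nearest valid cluster by
  centroid; alternatively a clara-style k-medoids on subsamples with k
  chosen by silhouette over tree cuts.  Agreement with reference labels is
  the Adjusted Rand Index.
- **Mantel statistic.**  Pearson correlation of the strictly-lower-triangle
  entries of two distance/similarity matrices.  HTS-fingerprint similarity
  uses pairwise Pearson correlation over shared assays, values clipped to
  [−20, 20]; when expression *distances* are correlated against fingerprint
  *correlations*, a strong association is therefore a *negative* Mantel
  value.
- **Promiscuity regression.**  RBF-kernel support-vector regression,
  out-of-fold predictions pooled per repeat, R² of predicted vs observed;
  hyperparameters (C ∈ {1, 10, 100}, ε ∈ {0.005, 0.02}, γ ∈ {scale, 0.03,
  0.003}) tuned by an inner grid on the training folds; mean ± SE over
  repeats.
- **Permutation nulls.**  Any label-dependent metric can be recomputed
  under random label permutations; we report the most extreme null value in
  the observed direction and p = (1 + #extreme)/(n_perm + 1), n_perm = 100
  by default.

## The synthetic data generator

Real reference datasets for this method are proprietary or large, so every
stage is exercised on synthetic data with known ground truth.  Sample s of
compound c in batch b is

    x[·, s] = effect[c] + batch_offset[b] + ε,   ε ~ N(0, noise² I),

where each compound's effect has exactly round(sparsity · n_genes) nonzero
entries (10% by default, scale 2 z-units), batch offsets are i.i.d.
per-batch per-gene draws (scale 1 by default), and replicates of a compound
are placed in distinct batches — the generative statement of "identical
treatment on a different day".  Compounds belong to latent clusters
(centroid + jitter on a shared sparse support); each cluster carries one
sub-micromolar target and a structure-cluster label corrupted at a small
rate (5%).  HTS fingerprints are noisy linear images of the true effects,
clipped to [−20, 20]; promiscuity is the fraction of fingerprint entries
beyond |z| = 3.  All randomness descends from one seed via
`numpy.random.SeedSequence.spawn`, one child stream per ingredient, so any
sub-structure is reproducible in isolation.

What the generator does *not* emulate: realistic gene–gene covariance
beyond cluster structure, dose–response, cell-line-specific biology, and
the way curated gene-set collections aggregate replicated biology.  Two
consequences seen in the benchmark: synthetic GSEA profiles do not
outperform raw z-scores at replicate retrieval (curated signatures would),
and promiscuity is more linearly recoverable from raw consensus z-scores
than from thresholded barcodes, since the synthetic promiscuity is a nearly
linear function of effect magnitude.  Passing tests therefore demonstrate
the mechanics and the denoising behaviour of the method under batch
corruption, not every ranking observed on real campaign data.

## The reference benchmark

`pertbarcode.benchmark.run_benchmark` is the package's end-to-end
experiment: 220 compounds profiled in duplicate across 20 batches with
batch offsets on the same scale as effect entries (the regime in which raw
Euclidean distances degrade), an 80/10/10 compound split, siamese training
(150 epochs, 64-pair minibatches — sized for the few hundred training pairs
this dataset yields), baseline fits, and the full metric battery on the
z-score, GSEA and barcode representations.  On one CPU it runs in under a
minute.  Under these conditions the barcode representation consistently
achieves a smaller median replicate rank, a more negative shared-target t,
a higher ARI against the true clusters and a higher Mantel correlation with
true-effect distances than the raw z-scores, and the trained model's test
pair accuracy exceeds the random and thresholding baselines.

## Numerical notes

- `softplus` and the sigmoid use the usual piecewise-stable forms; the
  margin cost is finite for arbitrarily large arguments.
- Gradients are exact for the sampled noise/mask realisation; dropout masks
  cancel analytically in the backward pass.  Tests verify backpropagation
  against central finite differences at 10⁻⁵ on a 6→4→3 model.
- Degenerate inputs fail loudly: zero vehicle MAD, empty replicate groups,
  constant regression outcomes, odd minibatch sizes, non-finite matrix
  entries, and both-groups-constant t statistics (defined as 0 when the
  means agree) are all explicit errors or documented conventions.

## Known limitations

Training is plain NumPy on one CPU and is sized for datasets of hundreds
to a few thousand profiles; the architecture is fixed to two hidden layers;
transcriptome-wide (22k-gene) inputs and hash-table retrieval
infrastructure are out of scope.  The clara and tree-cut clusterings are
deliberately simple, deterministic variants, not re-implementations of the
reference R packages.
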