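# pertbarcode

**Perturbation barcodes for high-throughput expression profiling.**

Large compound-profiling campaigns on the L1000 platform measure 978
landmark genes per treated sample and summarise each treatment as a vector
of robust z-scores against same-plate vehicle controls.  Day-to-day batch
effects make identically treated samples look different: in raw z-score
space, dozens to hundreds of unrelated profiles can sit closer to a sample
than its own biological replicate, which corrupts every downstream analysis
built on profile similarity (target inference, clustering, connectivity
queries).

`pertbarcode` addresses this with deep metric learning.  A siamese network
— two hidden layers of 400 and 100 noisy-sigmoid units with shared weights —
is trained on pairs of profiles to pull biological replicates below, and
push non-replicates above, a squared-distance margin:

$$y = \sigma(Wx + b + \mathcal{N}(0,\, 0.25\,I)), \qquad
  c = \mathrm{softplus}\!\left(1 - y\,(m - d^2)\right),\; m = 5,$$

where $d^2$ is the squared Euclidean distance between the two 100-unit
representations and $y = \pm 1$ marks replicate / non-replicate pairs.  The
pre-activation noise drives the hidden units towards saturation, so after
training the second hidden layer is almost binary; thresholding it at 0.5
turns each profile into a 100-bit **perturbation barcode**.  Distances
between barcodes recover replicate structure, shared-target relationships,
structural clustering and screening promiscuity better than the raw
z-scores they were derived from.

The package is aimed at computational biologists and cheminformaticians
working with Connectivity-Map-style data.  It provides:

- `pertbarcode.io` — GCT (`#1.2`/`#1.3`), GCTX (HDF5) and delimited-table
  readers/writers, robust z-scoring from plate intensities, sample
  metadata, compound annotations and GMT gene sets;
- `pertbarcode.simulate` — a generative model of L1000-like data (sparse
  compound effects, replicate structure, per-batch offsets, correlated
  annotations) with full ground truth, so everything is testable without
  proprietary data;
- `pertbarcode.pairs` — compound-level 80/10/10 splits and
  replicate/non-replicate pair streams;
- `pertbarcode.model` — the siamese network (NumPy, exact analytic
  gradients, RMSprop), barcode extraction and checkpointing;
- `pertbarcode.baselines` — random predictor, learned per-gene
  thresholding, random and learned linear projections, Wilcoxon rank-sum
  GSEA profiles;
- `pertbarcode.evaluate` — median replicate rank, shared-target t
  statistics, clustering + Adjusted Rand Index, Mantel correlations, SVR
  promiscuity regression, permutation nulls;
- a `pertbarcode` CLI with `simulate`, `train`, `encode`, `baselines` and
  `evaluate` subcommands.

## Worked example

Train on a synthetic campaign of 220 compounds profiled in duplicate, with
batch offsets as large as typical effect entries, then compare barcode and
raw z-score representations:

```python
from pertbarcode.benchmark import run_benchmark

results = run_benchmark(seed=0, with_gsea=False, with_svr=False,
                        with_permutation_null=False)
for name in ["random_baseline_accuracy_pct", "test_pair_accuracy_pct",
             "threshold_baseline_accuracy_pct",
             "median_replicate_rank_zscore", "median_replicate_rank_barcode",
             "shared_target_t_zscore", "shared_target_t_barcode",
             "true_cluster_ari_zscore", "true_cluster_ari_barcode",
             "true_effect_mantel_zscore", "true_effect_mantel_barcode"]:
    print(f"{name}: {results[name]:.3f}")
```

prints

```
random_baseline_accuracy_pct: 55.556
test_pair_accuracy_pct: 69.697
threshold_baseline_accuracy_pct: 63.636
median_replicate_rank_zscore: 40.500
median_replicate_rank_barcode: 5.000
shared_target_t_zscore: -28.219
shared_target_t_barcode: -58.777
true_cluster_ari_zscore: 0.070
true_cluster_ari_barcode: 0.300
true_effect_mantel_zscore: 0.222
true_effect_mantel_barcode: 0.409
```

Reading the numbers: a random predictor matched to the 1:2
replicate:non-replicate sampling ratio is right 55.6% of the time; the
trained model classifies 69.7% of held-out test pairs correctly, beating
the learned per-gene thresholding baseline (63.6%).  The median rank at
which a sample retrieves its own biological replicate drops from 40.5 (raw
z-scores) to 5 (barcodes; 2 is perfect).  Compound pairs sharing a
sub-micromolar target are more sharply closer than non-sharing pairs in
barcode space (t = −58.8 vs −28.2), barcode-derived clusters agree better
with the true compound clusters (ARI 0.30 vs 0.07), and barcode distances
correlate better with the true-effect distances (Mantel 0.41 vs 0.22) —
the barcode denoises exactly the structure the batch offsets obscured.

The same experiment is available from the shell:

```sh
pertbarcode simulate data/ --seed 0
pertbarcode train data/expression.gct data/metadata.tsv model.npz --epochs 150
pertbarcode encode data/expression.gct model.npz barcodes.tsv
pertbarcode evaluate data/metadata.tsv data/annotations.tsv data/expression.gct
```

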