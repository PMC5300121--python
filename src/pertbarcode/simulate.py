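"""Synthetic L1000-like data with known ground truth.

The generator emulates the statistical structure a replicate-based metric
learner relies on: each compound induces a sparse, reproducible expression
effect; biological replicates of a compound are treated on separate days and
therefore sit in different plate batches; every sample is corrupted by an
additive per-batch, per-gene offset plus i.i.d. measurement noise.  Compounds
belong to latent structural clusters whose members share correlated effects,
a structure-cluster label and a molecular target; HTS fingerprints are noisy
linear images of the true effects, and promiscuity is the fraction of
fingerprint entries beyond a hit threshold.

All randomness flows from ``SimulationConfig.seed`` through a
``numpy.random.SeedSequence`` spawning scheme (one child stream per
independent ingredient), so the full dataset is a deterministic function of
the config.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field

import numpy as np

from .io import (
    CompoundAnnotation,
    ExpressionMatrix,
    SampleMetadata,
    write_annotations,
    write_expression,
    write_metadata,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset",
           "dataset_to_files"]


@dataclass
class SimulationConfig:
    """Knobs of the generative model (all scales in z-score units).

    Defaults describe a moderately hard regime: batch offsets as large as the
    measurement noise and half the typical effect entry, ~10% of genes
    perturbed per compound, and 90% of compounds profiled in duplicate (the
    rest as singletons).
    """

    n_genes: int = 978
    n_compounds: int = 300
    replicate_fraction: float = 0.9   # compounds profiled as duplicates
    n_batches: int = 20
    effect_sparsity: float = 0.1      # fraction of genes perturbed per compound
    effect_scale: float = 2.0         # SD of nonzero effect entries
    batch_scale: float = 1.0          # SD of additive per-batch per-gene offsets
    noise_scale: float = 1.0          # SD of i.i.d. measurement noise
    n_targets: int = 25
    compounds_per_target_mean: float = 12.0
    cluster_jitter: float = 0.3       # per-compound jitter / centroid scale ratio
    cluster_label_noise: float = 0.05  # fraction of wrong structure-cluster labels
    n_assays: int = 150               # HTS fingerprint width
    hit_threshold: float = 3.0        # |z| above which an assay is a "hit"
    replicates_same_batch: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_compounds < 1 or self.n_batches < 1:
            raise ValueError("n_genes, n_compounds, n_batches must be positive")
        for name in ("effect_scale", "batch_scale", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("replicate_fraction", "effect_sparsity",
                     "cluster_label_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.replicates_same_batch and self.n_batches < 2:
            raise ValueError("need >= 2 batches to place replicates in distinct batches")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    expression: ExpressionMatrix
    metadata: list[SampleMetadata]
    annotations: list[CompoundAnnotation]
    true_effects: np.ndarray          # compounds x genes
    true_cluster_ids: np.ndarray      # latent cluster per compound
    compound_ids: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    def metadata_by_sample(self) -> dict[str, SampleMetadata]:
        return {m.sample_id: m for m in self.metadata}


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a dataset from the generative model described in the module docstring.

    Sample ``s`` of compound ``c`` in batch ``b`` has values
    ``effect[c] + batch_offset[b] + eps`` with ``eps ~ N(0, noise_scale^2 I)``;
    each compound's effect has exactly ``round(effect_sparsity * n_genes)``
    nonzero entries.
    """
    config.validate()
    n_replicated = int(round(config.replicate_fraction * config.n_compounds))
    if n_replicated < 1:
        raise ValueError(
            "replicate_fraction x n_compounds < 1: no replicate pairs can exist")

    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_cluster, rng_effect, rng_assign, rng_noise, rng_fp, rng_label, rng_batch = (
        np.random.default_rng(s) for s in streams)

    n_clusters = max(1, int(round(config.n_compounds / config.compounds_per_target_mean)))
    n_active = max(1, int(round(config.effect_sparsity * config.n_genes)))

    # Cluster centroids: sparse supports, shared within a cluster.
    supports = np.zeros((n_clusters, config.n_genes), dtype=bool)
    centroids = np.zeros((n_clusters, config.n_genes))
    for k in range(n_clusters):
        idx = rng_cluster.choice(config.n_genes, size=n_active, replace=False)
        supports[k, idx] = True
        centroids[k, idx] = rng_cluster.normal(0.0, config.effect_scale, size=n_active)

    cluster_of = rng_cluster.integers(0, n_clusters, size=config.n_compounds)

    # Compound effects: centroid + jitter restricted to the cluster support so
    # the per-compound nonzero count is exactly n_active.
    true_effects = np.zeros((config.n_compounds, config.n_genes))
    jitter_sd = config.cluster_jitter * config.effect_scale
    for c in range(config.n_compounds):
        k = cluster_of[c]
        row = centroids[k].copy()
        if jitter_sd > 0:
            jit = rng_effect.normal(0.0, jitter_sd, size=n_active)
            row[supports[k]] += jit
            # keep the support exact even if a jitter draw cancels the centroid
            zeroed = supports[k] & (row == 0)
            row[zeroed] = jitter_sd * 1e-6
        true_effects[c] = row

    # Replicate structure & batch placement.
    replicated = np.zeros(config.n_compounds, dtype=bool)
    replicated[rng_assign.choice(config.n_compounds, size=n_replicated,
                                 replace=False)] = True

    batch_offsets = rng_batch.normal(0.0, config.batch_scale,
                                     size=(config.n_batches, config.n_genes))

    compound_ids = [f"cpd_{c:04d}" for c in range(config.n_compounds)]
    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    columns: list[np.ndarray] = []
    for c in range(config.n_compounds):
        n_reps = 2 if replicated[c] else 1
        if n_reps == 2 and not config.replicates_same_batch:
            batches = rng_assign.choice(config.n_batches, size=2, replace=False)
        else:
            batches = rng_assign.integers(0, config.n_batches, size=n_reps)
        for r, b in enumerate(batches):
            sid = f"{compound_ids[c]}_rep{r}"
            sample_ids.append(sid)
            metadata.append(SampleMetadata(
                sample_id=sid, compound_id=compound_ids[c],
                replicate_group_id=f"rg_{c:04d}", batch_id=f"batch_{b:02d}",
                cell_line="PC3", dose=10.0))
            noise = rng_noise.normal(0.0, config.noise_scale, size=config.n_genes)
            columns.append(true_effects[c] + batch_offsets[b] + noise)

    expression = ExpressionMatrix([f"gene_{g:04d}" for g in range(config.n_genes)],
                                  sample_ids, np.column_stack(columns))

    # Annotations: one target per cluster, sub-uM potencies; HTS fingerprints
    # are noisy linear images of true effects; structure-cluster labels follow
    # the latent cluster with a small corruption rate.
    mixing = rng_fp.normal(0.0, 1.0, size=(config.n_genes, config.n_assays))
    mixing /= np.sqrt(config.n_genes * config.effect_sparsity)
    fp_clean = true_effects @ mixing
    fp_noisy = fp_clean * 2.0 + rng_fp.normal(0.0, 1.0,
                                              size=fp_clean.shape)
    fp_noisy = np.clip(fp_noisy, -20.0, 20.0)

    target_of_cluster = [f"target_{k % config.n_targets:03d}" for k in range(n_clusters)]
    annotations: list[CompoundAnnotation] = []
    for c in range(config.n_compounds):
        k = cluster_of[c]
        label = k
        if rng_label.random() < config.cluster_label_noise:
            label = rng_label.integers(0, n_clusters)
        potency = float(np.exp(rng_label.normal(np.log(0.1), 0.8)))
        potency = min(potency, 0.99)
        promiscuity = float(np.mean(np.abs(fp_noisy[c]) > config.hit_threshold))
        annotations.append(CompoundAnnotation(
            compound_id=compound_ids[c],
            targets=[(target_of_cluster[k], potency)],
            structure_cluster_id=f"sc_{label:03d}",
            hts_fingerprint=fp_noisy[c],
            promiscuity=promiscuity))

    return SyntheticDataset(expression=expression, metadata=metadata,
                            annotations=annotations, true_effects=true_effects,
                            true_cluster_ids=np.asarray(cluster_of),
                            compound_ids=compound_ids, config=config)


def dataset_to_files(dataset: SyntheticDataset, directory: str) -> dict[str, str]:
    """Write a dataset to ``directory`` in the package's interchange formats.

    Returns a name -> path map (expression GCT, metadata TSV, annotation TSV,
    fingerprint TSV, config JSON, true-effect TSV).
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.gct"),
        "metadata": os.path.join(directory, "metadata.tsv"),
        "annotations": os.path.join(directory, "annotations.tsv"),
        "fingerprints": os.path.join(directory, "hts_fingerprints.tsv"),
        "config": os.path.join(directory, "config.json"),
        "true_effects": os.path.join(directory, "true_effects.tsv"),
    }
    write_expression(dataset.expression, paths["expression"], "gct")
    write_metadata(dataset.metadata, paths["metadata"])
    write_annotations(dataset.annotations, paths["annotations"], paths["fingerprints"])
    if dataset.config is not None:
        dataset.config.to_json(paths["config"])
    effects = ExpressionMatrix(dataset.expression.gene_ids, list(dataset.compound_ids),
                               dataset.true_effects.T)
    write_expression(effects, paths["true_effects"], "delimited")
    return paths
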