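"""End-to-end benchmark: train the barcode model on synthetic data and run
the downstream metric battery against the raw z-score (and GSEA)
representations plus the baseline classifiers.

This is the package's reference experiment: a dataset of a few hundred
compounds profiled in duplicate with batch offsets as large as the typical
effect entry (the regime where raw Euclidean distances degrade), an 80/10/10
compound split, siamese training on replicate/non-replicate pairs, and the
evaluation metrics computed on every representation.  Problem sizes are kept
small enough to run on one CPU in a few minutes.
"""

from __future__ import annotations

import numpy as np

from . import baselines as bl
from . import evaluate as ev
from .model import ModelConfig, encode, pair_accuracy, train
from .pairs import sample_pairs, split_by_compound
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["benchmark_config", "model_config", "run_benchmark"]


def benchmark_config(seed: int, n_compounds: int = 220) -> SimulationConfig:
    """The benchmark's study conditions: duplicate profiling throughout and
    batch offsets on the same scale as effect entries."""
    return SimulationConfig(n_compounds=n_compounds, replicate_fraction=1.0,
                            batch_scale=2.0, effect_scale=2.0, seed=seed)


def model_config(n_genes: int = 978, seed: int = 0) -> ModelConfig:
    """Published architecture; epoch count and batch size sized for the
    benchmark's few hundred training pairs."""
    return ModelConfig(layer_sizes=(n_genes, 400, 100), epochs=150,
                       batch_size=64, seed=seed)


def run_benchmark(seed: int = 0, n_compounds: int = 220,
                  with_gsea: bool = True, with_svr: bool = True,
                  with_permutation_null: bool = True,
                  verbose: bool = False) -> dict[str, float]:
    """Run the full experiment and return a flat name -> value metric map."""
    config = benchmark_config(seed, n_compounds)
    ds = simulate_dataset(config)
    matrix = ds.expression

    split = split_by_compound(ds.metadata, seed=seed)
    train_pairs = sample_pairs(ds.metadata, split.train_compounds, seed=seed)
    val_pairs = sample_pairs(ds.metadata, split.validation_compounds, seed=seed + 1)
    test_pairs = sample_pairs(ds.metadata, split.test_compounds, seed=seed + 2)

    model = train(matrix, train_pairs, val_pairs,
                  model_config(matrix.n_genes, seed=seed), verbose=verbose)

    results: dict[str, float] = {}
    accuracy, f1 = bl.random_baseline_metrics(1.0 / 3.0)
    results["random_baseline_accuracy_pct"] = 100.0 * accuracy
    results["random_baseline_f1"] = f1
    results["test_pair_accuracy_pct"] = 100.0 * pair_accuracy(model, matrix, test_pairs)
    results["best_validation_accuracy_pct"] = 100.0 * max(
        h["val_accuracy"] for h in model.training_history)

    thr = bl.fit_threshold_model(matrix, train_pairs, seed=seed, epochs=60)
    results["threshold_baseline_accuracy_pct"] = 100.0 * bl.threshold_pair_accuracy(
        matrix, test_pairs, thr)
    rand_proj = bl.random_projection_model(matrix.n_genes, k=100, seed=seed)
    results["random_projection_accuracy_pct"] = 100.0 * bl.projection_pair_accuracy(
        matrix, test_pairs, rand_proj, binarize=True)
    linear = bl.fit_projection_model(matrix, train_pairs, k=100, seed=seed,
                                     epochs=60)
    results["linear_model_accuracy_pct"] = 100.0 * bl.projection_pair_accuracy(
        matrix, test_pairs, linear)

    # representations: raw z-scores, barcode bits, optionally GSEA profiles
    z = matrix.values.T
    activations = encode(matrix, model)
    bits = (activations >= 0.5).astype(float)
    representations = {"zscore": (z, z), "barcode": (bits, activations)}
    if with_gsea:
        sets = bl.make_synthetic_gene_sets(matrix.gene_ids, ds.true_effects,
                                           n_sets=100, set_size=30, seed=seed)
        gsea = bl.gsea_profile(matrix, sets).T
        representations["gsea"] = (gsea, gsea)

    cl_index = {c: i for i, c in enumerate(ds.compound_ids)}
    consensus_dm: dict[str, ev.DistanceMatrix] = {}
    consensus_rows: dict[str, np.ndarray] = {}
    compound_order: list[str] = []
    for name, (features, raw) in representations.items():
        dm = ev.DistanceMatrix.from_features(features, matrix.sample_ids)
        median_rank, _ = ev.replicate_rank_summary(dm, ds.metadata)
        results[f"median_replicate_rank_{name}"] = median_rank
        cpds, rows = ev.consensus_by_compound(raw, matrix.sample_ids, ds.metadata,
                                              binarize=(name == "barcode"))
        compound_order = cpds
        consensus_rows[name] = rows
        cdm = ev.DistanceMatrix.from_features(rows, cpds)
        consensus_dm[name] = cdm
        results[f"shared_target_t_{name}"] = ev.shared_target_t(cdm, ds.annotations)
        truth = [int(ds.true_cluster_ids[cl_index[c]]) for c in cpds]
        labels = ev.cluster_expression(rows, method="tree_cut", seed=seed)
        results[f"true_cluster_ari_{name}"] = ev.adjusted_rand_index(labels, truth)

    true_rows = np.vstack([ds.true_effects[cl_index[c]] for c in compound_order])
    true_dm = ev.DistanceMatrix.from_features(true_rows, compound_order)
    for name in representations:
        results[f"true_effect_mantel_{name}"] = ev.mantel_correlation(
            consensus_dm[name], true_dm)

    fp_ids, fp_corr = ev.hts_fp_correlation_matrix(ds.annotations)
    fp_pos = {c: i for i, c in enumerate(fp_ids)}
    sel = [fp_pos[c] for c in compound_order]
    for name in representations:
        results[f"hts_fp_mantel_{name}"] = ev.mantel_correlation(
            consensus_dm[name].square(), fp_corr[np.ix_(sel, sel)])

    if with_svr:
        prom = {a.compound_id: a.promiscuity for a in ds.annotations}
        y = np.asarray([prom[c] for c in compound_order])
        for name in representations:
            r2, se = ev.promiscuity_regression(consensus_rows[name], y, seed=seed)
            results[f"promiscuity_svr_r2_{name}"] = r2
            results[f"promiscuity_svr_r2_se_{name}"] = se

    if with_permutation_null:
        null = _shared_target_permutation_null(consensus_dm["barcode"],
                                               ds, compound_order, seed)
        results["shared_target_t_barcode_null_min"] = null["null_extreme"]
        results["shared_target_t_barcode_null_p"] = null["p_value"]

    return results


def _shared_target_permutation_null(cdm: ev.DistanceMatrix, ds,
                                    compound_order: list[str],
                                    seed: int, n_perm: int = 100) -> dict:
    """Permutation null of the pooled shared-target t for the barcode
    representation, permuting the compound -> target assignment."""
    targets_of = {a.compound_id: set(a.sub_micromolar_targets())
                  for a in ds.annotations}
    all_targets = sorted(set().union(*targets_of.values()))
    t_index = {t: j for j, t in enumerate(all_targets)}
    T = np.zeros((len(compound_order), len(all_targets)), dtype=bool)
    for i, c in enumerate(compound_order):
        for t in targets_of[c]:
            T[i, t_index[t]] = True
    square = cdm.square()
    iu = np.triu_indices(len(compound_order), k=1)
    dists = square[iu]

    def t_of(order: np.ndarray) -> float:
        sharing = (T[order] @ T[order].T)[iu] > 0
        return ev._t_statistic(dists[sharing], dists[~sharing], equal_var=False)

    return ev.permutation_null(t_of, np.arange(len(compound_order)),
                               n_perm=n_perm, seed=seed, direction="less")
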