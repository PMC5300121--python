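"""Baseline representations and classifiers the barcode is compared against.

Four families: (1) an input-independent random predictor matched to the
empirical replicate frequency; (2) per-sample binarisation of the z-scores by
shared or per-gene thresholds on the signed or absolute scale, with
thresholds learned by gradient descent on the same margin cost as the
network; (3) random sign projections in the style of locality-sensitive
hashing; (4) learned linear projections (the linear model), trained with the
same cost and optimiser as the network.  A Wilcoxon rank-sum GSEA profile
(one enrichment z statistic per gene set) provides the knowledge-based
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import ExpressionMatrix
from .model import sigmoid
from .pairs import PairSet, pairs_to_stream

__all__ = ["ThresholdModel", "ProjectionModel", "GeneSetCollection",
           "random_baseline_metrics", "simulate_random_baseline",
           "binarize_by_threshold", "fit_threshold_model", "project",
           "fit_projection_model", "random_projection_model", "gsea_profile",
           "make_synthetic_gene_sets", "representation_pair_accuracy"]


# ---------------------------------------------------------------------------
# Random predictor
# ---------------------------------------------------------------------------


def random_baseline_metrics(replicate_fraction: float) -> tuple[float, float]:
    """Expected accuracy and F1 of a label-frequency-matched random predictor.

    A predictor that emits +1 with probability q = replicate_fraction,
    independent of the input, on a stream whose true replicate fraction is
    also q, has accuracy q^2 + (1-q)^2 and precision = recall = F1 = q.
    """
    q = float(replicate_fraction)
    if not 0.0 < q < 1.0:
        raise ValueError("replicate_fraction must be in (0, 1)")
    accuracy = q * q + (1.0 - q) * (1.0 - q)
    return accuracy, q


def simulate_random_baseline(replicate_fraction: float, n_trials: int,
                             seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo accuracy and F1 of the random predictor (for cross-checks)."""
    rng = np.random.default_rng(seed)
    q = float(replicate_fraction)
    truth = rng.random(n_trials) < q
    pred = rng.random(n_trials) < q
    accuracy = float(np.mean(truth == pred))
    tp = float(np.sum(truth & pred))
    fp = float(np.sum(~truth & pred))
    fn = float(np.sum(truth & ~pred))
    f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
    return accuracy, f1


# ---------------------------------------------------------------------------
# Thresholding models
# ---------------------------------------------------------------------------


@dataclass
class ThresholdModel:
    """Binarise z-scores by a shared or per-gene threshold.

    ``mode`` combines the threshold scope ('shared' or 'per_gene') with the
    scale ('signed': bit = 1 iff z > t; 'absolute': bit = 1 iff |z| > t).
    """

    scope: str = "per_gene"      # shared | per_gene
    scale: str = "signed"        # signed | absolute
    thresholds: np.ndarray | float = 0.0
    margin: float = 5.0
    train_accuracy: float | None = None
    validation_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.scope not in ("shared", "per_gene"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scale not in ("signed", "absolute"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scope == "per_gene":
            self.thresholds = np.asarray(self.thresholds, dtype=float)


def binarize_by_threshold(matrix: ExpressionMatrix | np.ndarray,
                          model: ThresholdModel) -> np.ndarray:
    """Binary genes x samples matrix; strictly-greater comparisons (z = t -> 0)."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    if model.scope == "per_gene":
        t = np.asarray(model.thresholds, dtype=float)
        if t.shape != (values.shape[0],):
            raise ValueError(f"per-gene thresholds length {t.shape} does not "
                             f"match gene count {values.shape[0]}")
        t = t[:, None]
    else:
        t = float(model.thresholds)
    base = np.abs(values) if model.scale == "absolute" else values
    return (base > t).astype(np.int8)


def fit_threshold_model(matrix: ExpressionMatrix, pairs: PairSet,
                        scope: str = "per_gene", scale: str = "signed",
                        margin: float = 5.0, temperature: float = 0.5,
                        learning_rate: float = 0.05, epochs: int = 200,
                        seed: int = 0,
                        val_pairs: PairSet | None = None) -> ThresholdModel:
    """Learn thresholds by gradient descent on a sigmoid-relaxed binarisation.

    The hard bit 1{z > t} is relaxed to sigma((z - t) / temperature) (or on
    |z| for the absolute scale) and the same squared-distance margin cost as
    the network is minimised over the pair set by RMSprop.
    """
    if len(pairs) == 0:
        raise ValueError("pair set is empty")
    n_genes = matrix.n_genes
    rng = np.random.default_rng(seed)
    t = np.full(n_genes, 1.0) if scope == "per_gene" else np.array([1.0])
    t = t + rng.normal(0, 0.01, size=t.shape)
    cache = np.zeros_like(t)
    decay, eps = 0.9, 1e-8
    for epoch in range(epochs):
        for X, labels in pairs_to_stream(matrix, pairs, batch_size=512,
                                         shuffle=True, seed=seed * 100003 + epoch):
            cost, g_t = _threshold_cost_grad(X, labels, t, scope, scale,
                                             margin, temperature)
            if not np.isfinite(cost):
                raise RuntimeError(f"threshold fit diverged at epoch {epoch}")
            cache = decay * cache + (1 - decay) * g_t ** 2
            t -= learning_rate * g_t / (np.sqrt(cache) + eps)
    model = ThresholdModel(scope=scope, scale=scale,
                           thresholds=t if scope == "per_gene" else float(t[0]),
                           margin=margin)
    model.train_accuracy = threshold_pair_accuracy(matrix, pairs, model,
                                                   temperature=temperature)
    if val_pairs is not None:
        model.validation_accuracy = threshold_pair_accuracy(
            matrix, val_pairs, model, temperature=temperature)
    return model


def _threshold_cost_grad(X: np.ndarray, labels: np.ndarray, t: np.ndarray,
                         scope: str, scale: str, margin: float,
                         temperature: float) -> tuple[float, np.ndarray]:
    """Mean margin cost of the relaxed binarisation and its exact gradient
    in the thresholds (the analytic counterpart finite differences verify)."""
    labels = np.asarray(labels, dtype=float)
    base = np.abs(X) if scale == "absolute" else X
    tt = t if scope == "per_gene" else t[0]
    r = sigmoid((base - tt) / temperature)
    diff = r[0::2] - r[1::2]
    d2 = np.sum(diff * diff, axis=1)
    arg = 1.0 - labels * (margin - d2)
    cost = float(np.mean(np.maximum(arg, 0.0) + np.log1p(np.exp(-np.abs(arg)))))
    dcost_dd2 = sigmoid(arg) * labels / labels.shape[0]
    g_r = np.empty_like(r)
    g_r[0::2] = (2.0 * dcost_dd2)[:, None] * diff
    g_r[1::2] = -g_r[0::2]
    # d r / d t = -r (1 - r) / temperature
    g_t_full = -(g_r * r * (1.0 - r) / temperature).sum(axis=0)
    g_t = g_t_full if scope == "per_gene" else np.array([g_t_full.sum()])
    return cost, g_t


def threshold_pair_accuracy(matrix: ExpressionMatrix, pairs: PairSet,
                            model: ThresholdModel,
                            temperature: float = 0.5) -> float:
    """Pair accuracy of the relaxed representation under the margin rule."""
    correct = 0
    tt = model.thresholds if model.scope == "per_gene" else float(model.thresholds)
    for X, labels in pairs_to_stream(matrix, pairs, batch_size=512):
        base = np.abs(X) if model.scale == "absolute" else X
        r = sigmoid((base - tt) / temperature)
        diff = r[0::2] - r[1::2]
        d2 = np.sum(diff * diff, axis=1)
        pred = np.where(d2 < model.margin, 1, -1)
        correct += int(np.sum(pred == labels))
    return correct / len(pairs)


# ---------------------------------------------------------------------------
# Projection models
# ---------------------------------------------------------------------------


@dataclass
class ProjectionModel:
    """Linear map of a profile to k features: h = P^T z.

    With ``learned`` False the projection is a fixed random Gaussian matrix
    (LSH-style); sign-binarised codes use the rule bit = 1 iff h >= 0.
    """

    projection: np.ndarray    # genes x k
    learned: bool = False
    margin: float = 5.0
    train_accuracy: float | None = None
    validation_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.projection = np.asarray(self.projection, dtype=float)
        if self.projection.ndim != 2 or self.projection.shape[1] < 1:
            raise ValueError("projection must be genes x k with k >= 1")


def random_projection_model(n_genes: int, k: int = 100, seed: int = 0,
                            margin: float = 5.0) -> ProjectionModel:
    rng = np.random.default_rng(seed)
    return ProjectionModel(rng.normal(0.0, 1.0, size=(n_genes, k)),
                           learned=False, margin=margin)


def project(matrix: ExpressionMatrix | np.ndarray, model: ProjectionModel,
            binarize: bool = False) -> np.ndarray:
    """Project to k x samples features; optionally sign-hash (h >= 0 -> 1)."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    if values.shape[0] != model.projection.shape[0]:
        raise ValueError(f"gene count {values.shape[0]} does not match "
                         f"projection rows {model.projection.shape[0]}")
    h = model.projection.T @ values
    if binarize:
        return (h >= 0).astype(np.int8)
    return h


def fit_projection_model(matrix: ExpressionMatrix, pairs: PairSet,
                         k: int = 100, margin: float = 5.0,
                         learning_rate: float = 1e-3, epochs: int = 100,
                         seed: int = 0,
                         val_pairs: PairSet | None = None) -> ProjectionModel:
    """Learn the projections (a linear model) under the shared margin cost."""
    if len(pairs) == 0:
        raise ValueError("pair set is empty")
    rng = np.random.default_rng(seed)
    n_genes = matrix.n_genes
    P = rng.normal(0.0, 1.0 / np.sqrt(n_genes), size=(n_genes, k))
    cache = np.zeros_like(P)
    decay, eps = 0.9, 1e-8
    for epoch in range(epochs):
        for X, labels in pairs_to_stream(matrix, pairs, batch_size=512,
                                         shuffle=True, seed=seed * 100003 + epoch):
            H = X @ P
            diff = H[0::2] - H[1::2]
            d2 = np.sum(diff * diff, axis=1)
            arg = 1.0 - labels * (margin - d2)
            if not np.all(np.isfinite(arg)):
                raise RuntimeError(f"projection fit diverged at epoch {epoch}")
            dcost_dd2 = sigmoid(arg) * labels / labels.shape[0]
            g_H = np.empty_like(H)
            g_H[0::2] = (2.0 * dcost_dd2)[:, None] * diff
            g_H[1::2] = -g_H[0::2]
            g_P = X.T @ g_H
            cache = decay * cache + (1 - decay) * g_P ** 2
            P -= learning_rate * g_P / (np.sqrt(cache) + eps)
    model = ProjectionModel(P, learned=True, margin=margin)
    model.train_accuracy = projection_pair_accuracy(matrix, pairs, model)
    if val_pairs is not None:
        model.validation_accuracy = projection_pair_accuracy(matrix, val_pairs, model)
    return model


def projection_pair_accuracy(matrix: ExpressionMatrix, pairs: PairSet,
                             model: ProjectionModel,
                             binarize: bool = False) -> float:
    correct = 0
    for X, labels in pairs_to_stream(matrix, pairs, batch_size=512):
        H = X @ model.projection
        if binarize:
            H = (H >= 0).astype(float)
        diff = H[0::2] - H[1::2]
        d2 = np.sum(diff * diff, axis=1)
        pred = np.where(d2 < model.margin, 1, -1)
        correct += int(np.sum(pred == labels))
    return correct / len(pairs)


def representation_pair_accuracy(features: np.ndarray, sample_ids: list[str],
                                 pairs: PairSet, margin: float = 5.0) -> float:
    """Margin-rule pair accuracy for an arbitrary samples x features matrix."""
    index = {s: i for i, s in enumerate(sample_ids)}
    correct = 0
    for a, b, label in pairs.pairs:
        diff = features[index[a]] - features[index[b]]
        pred = 1 if float(diff @ diff) < margin else -1
        correct += int(pred == label)
    return correct / len(pairs)


# ---------------------------------------------------------------------------
# GSEA profiles (Wilcoxon rank-sum z statistics)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared gene universe."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def gsea_profile(matrix: ExpressionMatrix,
                 collection: GeneSetCollection) -> np.ndarray:
    """Per-sample enrichment z statistic for each gene set (sets x samples).

    For each set, the z-scores of in-set genes are compared with all other
    genes by a two-sample Wilcoxon rank-sum test using midranks for ties,
    the tie-corrected normal approximation and a continuity correction.
    The sign is positive when in-set genes rank higher.  Sets with no genes
    in the matrix's universe yield NaN.
    """
    values = matrix.values
    n = values.shape[0]
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    ranks = np.apply_along_axis(rankdata, 0, values)  # midranks per sample

    # tie correction term per sample: sum over tie groups of (t^3 - t)
    tie_terms = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        tie_terms[j] = float(np.sum(counts ** 3 - counts))

    out = np.full((len(collection.sets), values.shape[1]), np.nan)
    for s, (name, genes) in enumerate(collection.sets.items()):
        idx = [gene_index[g] for g in genes if g in gene_index]
        n1 = len(idx)
        n2 = n - n1
        if n1 == 0 or n2 == 0:
            continue
        rank_sum = ranks[idx].sum(axis=0)
        mu = n1 * (n + 1) / 2.0
        var = (n1 * n2 / 12.0) * ((n + 1) - tie_terms / (n * (n - 1)))
        sigma_ = np.sqrt(np.maximum(var, 0.0))
        centered = rank_sum - mu
        corrected = centered - 0.5 * np.sign(centered)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sigma_ > 0, corrected / sigma_, 0.0)
        out[s] = z
    return out


def make_synthetic_gene_sets(gene_ids: list[str], true_effects: np.ndarray,
                             n_sets: int = 50, set_size: int = 30,
                             signal_fraction: float = 0.7,
                             seed: int = 0) -> GeneSetCollection:
    """Gene sets enriched in the perturbed genes of simulated compounds.

    Each set draws ``signal_fraction`` of its members from the nonzero-effect
    genes of one randomly chosen compound and the rest uniformly, emulating
    curated signature collections that partially overlap real perturbations.
    """
    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        c = rng.integers(0, true_effects.shape[0])
        perturbed = np.flatnonzero(true_effects[c])
        n_signal = min(int(round(signal_fraction * set_size)), perturbed.size)
        chosen = set(rng.choice(perturbed, size=n_signal, replace=False).tolist())
        while len(chosen) < min(set_size, n_genes):
            chosen.add(int(rng.integers(0, n_genes)))
        sets[f"set_{s:03d}"] = [gene_ids[i] for i in sorted(chosen)]
    return GeneSetCollection(sets)
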