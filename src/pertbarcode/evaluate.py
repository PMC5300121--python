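"""The downstream metric battery applied uniformly to every representation.

Replicate retrieval (median rank of a sample's biological replicate among
all samples by Euclidean distance), shared-target similarity (Welch t
statistic contrasting consensus-profile distances of compound pairs that do
and do not share a sub-micromolar target; negative = sharing pairs closer),
clustering overlap (Adjusted Rand Index between expression-derived clusters
and reference labels), Mantel correlation between distance/similarity
matrices, cross-validated SVR prediction of compound promiscuity, and
permutation nulls for any of the above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, ttest_ind
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from .io import CompoundAnnotation, SampleMetadata

__all__ = ["DistanceMatrix", "EvaluationReport", "replicate_rank_summary",
           "shared_target_t", "cluster_expression", "adjusted_rand_index",
           "mantel_correlation", "hts_fp_correlation_matrix",
           "promiscuity_regression", "permutation_null",
           "consensus_by_compound"]


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean distances stored as a condensed lower triangle."""

    sample_ids: list[str]
    condensed: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        expected = n * (n - 1) // 2
        self.condensed = np.asarray(self.condensed, dtype=float)
        if self.condensed.shape != (expected,):
            raise ValueError(f"condensed length {self.condensed.shape} does not "
                             f"match {n} samples (expected {expected})")
        if np.any(self.condensed < 0):
            raise ValueError("distances must be nonnegative")

    @classmethod
    def from_features(cls, features: np.ndarray, sample_ids: list[str]) -> "DistanceMatrix":
        """Euclidean distances between rows of a samples x features matrix."""
        features = np.asarray(features, dtype=float)
        if features.shape[0] != len(sample_ids):
            raise ValueError("feature rows must match sample_ids")
        return cls(list(sample_ids), pdist(features, metric="euclidean"))

    def square(self) -> np.ndarray:
        return squareform(self.condensed)


@dataclass
class EvaluationReport:
    """Named metric values for one representation, plus permutation nulls."""

    representation: str
    metrics: dict[str, float] = field(default_factory=dict)
    permutation_nulls: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"representation": self.representation,
                       "metrics": self.metrics,
                       "permutation_nulls": self.permutation_nulls}, fh, indent=2)


# ---------------------------------------------------------------------------
# Replicate retrieval
# ---------------------------------------------------------------------------


def replicate_rank_summary(distances: DistanceMatrix,
                           metadata: list[SampleMetadata]
                           ) -> tuple[float, dict[str, float]]:
    """Median rank at which each sample retrieves its biological replicate.

    For every sample with at least one replicate, all samples (including the
    query itself, pinned at rank 1) are ranked by ascending distance with
    ties broken by average rank; the rank of the nearest replicate is
    recorded.  Returns the median over query samples and the per-sample
    ranks.  Rank 2 is the best achievable value.
    """
    meta = {m.sample_id: m for m in metadata}
    ids = distances.sample_ids
    group_of = {s: meta[s].replicate_group_id for s in ids if s in meta}
    members: dict[str, list[int]] = {}
    for i, s in enumerate(ids):
        members.setdefault(group_of[s], []).append(i)
    square = distances.square()
    ranks: dict[str, float] = {}
    for i, s in enumerate(ids):
        partners = [j for j in members[group_of[s]] if j != i]
        if not partners:
            continue
        row = square[i].copy()
        row[i] = -np.inf  # the query itself always ranks first
        all_ranks = rankdata(row, method="average")
        ranks[s] = float(min(all_ranks[j] for j in partners))
    if not ranks:
        raise ValueError("no sample has a biological replicate")
    return float(np.median(list(ranks.values()))), ranks


# ---------------------------------------------------------------------------
# Shared-target similarity
# ---------------------------------------------------------------------------


def shared_target_t(distances: DistanceMatrix,
                    annotations: list[CompoundAnnotation],
                    potency_cutoff: float = 1.0,
                    pooled: bool = True,
                    equal_var: bool = False) -> float:
    """t statistic contrasting distances of target-sharing vs non-sharing pairs.

    ``distances`` holds per-compound consensus representations.  Only
    compounds with at least one target below ``potency_cutoff`` (uM) enter.
    Pooled mode runs one two-sample t over all pairs; otherwise a t is
    computed per target (its sharing pairs vs the pairs not sharing it) and
    the mean over targets is returned.  Welch's t by default.  Negative
    values mean sharing pairs are closer.
    """
    targets_of = {}
    for a in annotations:
        subs = set(a.sub_micromolar_targets(potency_cutoff))
        if subs:
            targets_of[a.compound_id] = subs
    idx = [i for i, c in enumerate(distances.sample_ids) if c in targets_of]
    if len(idx) < 3:
        raise ValueError("need >= 3 annotated compounds")
    square = distances.square()
    compounds = [distances.sample_ids[i] for i in idx]
    pair_dist = []
    pair_shared = []
    pair_targets = []
    for a_pos in range(len(idx)):
        for b_pos in range(a_pos + 1, len(idx)):
            ta = targets_of[compounds[a_pos]]
            tb = targets_of[compounds[b_pos]]
            pair_dist.append(square[idx[a_pos], idx[b_pos]])
            pair_shared.append(bool(ta & tb))
            pair_targets.append(ta | tb if ta & tb else frozenset())
    pair_dist = np.asarray(pair_dist)
    pair_shared = np.asarray(pair_shared)
    if pooled:
        sharing = pair_dist[pair_shared]
        non_sharing = pair_dist[~pair_shared]
        if sharing.size < 2:
            raise ValueError("sharing-pair group has fewer than 2 pairs")
        if non_sharing.size < 2:
            raise ValueError("non-sharing-pair group has fewer than 2 pairs")
        return _t_statistic(sharing, non_sharing, equal_var)
    all_targets = sorted(set().union(*targets_of.values()))
    stats = []
    for target in all_targets:
        has = np.asarray([target in targets_of[c] for c in compounds])
        share_mask = []
        k = 0
        for a_pos in range(len(idx)):
            for b_pos in range(a_pos + 1, len(idx)):
                share_mask.append(has[a_pos] and has[b_pos])
                k += 1
        share_mask = np.asarray(share_mask)
        sharing = pair_dist[share_mask]
        others = pair_dist[~share_mask]
        if sharing.size >= 2 and others.size >= 2:
            stats.append(_t_statistic(sharing, others, equal_var))
    if not stats:
        raise ValueError("no target has >= 2 sharing pairs")
    return float(np.mean(stats))


def _t_statistic(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: both groups constant; equal means -> no difference
        if np.mean(a) == np.mean(b):
            return 0.0
        return float(-np.inf if np.mean(a) < np.mean(b) else np.inf)
    result = ttest_ind(a, b, equal_var=equal_var)
    return float(result.statistic)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_expression(features: np.ndarray, method: str = "tree_cut",
                       min_cluster_size: int = 3, max_k: int = 20,
                       seed: int = 0) -> np.ndarray:
    """Cluster compounds from a compounds x features representation.

    ``tree_cut``: average-linkage hierarchical clustering on Euclidean
    distances, cut at the dendrogram height with the best silhouette score (a
    deterministic simplification of adaptive tree cutting); undersized
    clusters (< ``min_cluster_size``) are merged into the valid cluster with
    the nearest centroid.  ``clara``: k-medoid clustering on subsamples with
    k chosen by silhouette over cuts of a hierarchical tree built on a
    subsample.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < max(3, min_cluster_size):
        raise ValueError("fewer compounds than the minimum cluster size")
    if method == "tree_cut":
        return _tree_cut_labels(features, min_cluster_size)
    if method == "clara":
        return _clara_labels(features, min_cluster_size, max_k, seed)
    raise ValueError(f"unknown clustering method {method!r}")


def _tree_cut_labels(features: np.ndarray, min_size: int) -> np.ndarray:
    n = features.shape[0]
    condensed = pdist(features)
    Z = linkage(condensed, method="average")
    square = squareform(condensed)
    best_labels = None
    best_score = -np.inf
    seen: set[int] = set()
    for h in np.unique(Z[:, 2]):
        labels = fcluster(Z, t=h, criterion="distance")
        k = len(np.unique(labels))
        if k < 2 or k >= n or k in seen:
            continue
        seen.add(k)
        score = silhouette_score(square, labels, metric="precomputed")
        if score > best_score:
            best_score = score
            best_labels = labels
    if best_labels is None:  # all points coincide; a single cluster
        return np.zeros(n, dtype=int)
    return _merge_small_clusters(features, np.asarray(best_labels), min_size)


def _merge_small_clusters(features: np.ndarray, labels: np.ndarray,
                          min_size: int) -> np.ndarray:
    labels = labels.copy()
    unique, counts = np.unique(labels, return_counts=True)
    valid = unique[counts >= min_size]
    if valid.size == 0:
        return np.zeros_like(labels)
    centroids = {c: features[labels == c].mean(axis=0) for c in valid}
    for c in unique[counts < min_size]:
        for i in np.flatnonzero(labels == c):
            best = min(valid, key=lambda v: float(np.sum((features[i] - centroids[v]) ** 2)))
            labels[i] = best
    # relabel to consecutive integers for cleanliness
    _, relabeled = np.unique(labels, return_inverse=True)
    return relabeled


def _clara_labels(features: np.ndarray, min_size: int, max_k: int,
                  seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = features.shape[0]
    sub_n = min(n, max(40, 5 * max_k))
    sub = rng.choice(n, size=sub_n, replace=False)
    Z = linkage(pdist(features[sub]), method="average")
    best_k, best_sil = 2, -np.inf
    for k in range(2, min(max_k, sub_n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(features[sub], labels)
        if sil > best_sil:
            best_sil, best_k = sil, k
    k = best_k
    square = None
    best_labels, best_cost = None, np.inf
    for _ in range(5):  # clara: best k-medoids over several subsamples
        sample = rng.choice(n, size=min(n, sub_n), replace=False)
        medoids = _k_medoids(features[sample], k, rng)
        medoid_rows = features[sample][medoids]
        d = _cross_distances(features, medoid_rows)
        cost = float(d.min(axis=1).sum())
        if cost < best_cost:
            best_cost = cost
            best_labels = d.argmin(axis=1)
    return np.asarray(best_labels)


def _k_medoids(X: np.ndarray, k: int, rng: np.random.Generator,
               max_iter: int = 50) -> np.ndarray:
    n = X.shape[0]
    d = squareform(pdist(X))
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        assign = d[:, medoids].argmin(axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(assign == j)
            if members.size == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[within.argmin()]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return medoids


def _cross_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.sqrt(np.maximum(
        (A ** 2).sum(1)[:, None] + (B ** 2).sum(1)[None, :] - 2 * A @ B.T, 0.0))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (1 identical, ~0 independent)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


# ---------------------------------------------------------------------------
# Mantel correlation & HTS fingerprints
# ---------------------------------------------------------------------------


def mantel_correlation(matrix_a, matrix_b) -> float:
    """Pearson correlation of the strictly-lower-triangle entries of two
    square distance/similarity matrices (or DistanceMatrix objects)."""
    A = _as_square(matrix_a)
    B = _as_square(matrix_b)
    if A.shape != B.shape:
        raise ValueError("matrices must describe the same sample set")
    if isinstance(matrix_a, DistanceMatrix) and isinstance(matrix_b, DistanceMatrix):
        if matrix_a.sample_ids != matrix_b.sample_ids:
            raise ValueError("sample identifier order differs between matrices")
    tri = np.tril_indices_from(A, k=-1)
    a, b = A[tri], B[tri]
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 finite pairwise entries in common")
    return float(np.corrcoef(a[mask], b[mask])[0, 1])


def _as_square(m) -> np.ndarray:
    if isinstance(m, DistanceMatrix):
        return m.square()
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix or DistanceMatrix")
    return m


def hts_fp_correlation_matrix(annotations: list[CompoundAnnotation],
                              min_overlap: int = 3) -> tuple[list[str], np.ndarray]:
    """Pairwise Pearson correlation of HTS fingerprints over shared assays.

    Fingerprint values are clipped to [-20, 20] on construction; assays
    missing (NaN) in either compound are ignored, and pairs with fewer than
    ``min_overlap`` shared assays get NaN.
    """
    with_fp = [a for a in annotations if a.hts_fingerprint is not None]
    if len(with_fp) < 2:
        raise ValueError("need at least 2 compounds with fingerprints")
    ids = [a.compound_id for a in with_fp]
    F = np.vstack([a.hts_fingerprint for a in with_fp])
    n = len(ids)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(F[i]) & np.isfinite(F[j])
            if mask.sum() < min_overlap:
                continue
            x, y = F[i, mask], F[j, mask]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            out[i, j] = out[j, i] = float(np.corrcoef(x, y)[0, 1])
    return ids, out


# ---------------------------------------------------------------------------
# Promiscuity regression
# ---------------------------------------------------------------------------


def promiscuity_regression(features: np.ndarray, promiscuity: np.ndarray,
                           cv_folds: int = 5, n_repeats: int = 3,
                           seed: int = 0) -> tuple[float, float]:
    """Cross-validated R^2 of an RBF support-vector regression.

    Per repeat: out-of-fold predictions are pooled and R^2 of predicted vs
    observed promiscuity computed; hyperparameters are tuned by a small grid
    on each training fold.  Returns (mean R^2, standard error over repeats).
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(promiscuity, dtype=float)
    if np.std(y) == 0:
        raise ValueError("promiscuity is constant; R^2 undefined")
    if features.shape[0] // cv_folds < 1 or features.shape[0] < 2 * cv_folds:
        raise ValueError("too few compounds for the requested fold count")
    grid = {"C": [1.0, 10.0, 100.0], "epsilon": [0.005, 0.02],
            "gamma": ["scale", 0.03, 0.003]}
    r2s = []
    for rep in range(n_repeats):
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed + rep)
        pred = np.empty_like(y)
        for train_idx, test_idx in kf.split(features):
            search = GridSearchCV(SVR(kernel="rbf", gamma="scale"), grid, cv=3,
                                  scoring="neg_mean_squared_error")
            search.fit(features[train_idx], y[train_idx])
            pred[test_idx] = search.predict(features[test_idx])
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2s.append(1.0 - ss_res / ss_tot)
    r2s = np.asarray(r2s)
    se = float(r2s.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    return float(r2s.mean()), se


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------


def permutation_null(metric, labels, n_perm: int = 100, seed: int = 0,
                     direction: str = "greater") -> dict:
    """Permutation null for any label-dependent metric.

    ``metric(labels)`` is evaluated on the observed labels and on ``n_perm``
    random permutations.  The extreme null value in the observed effect's
    direction and the empirical p value
    ``(1 + #{null at least as extreme}) / (n_perm + 1)`` are returned.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(metric(labels))
    nulls = np.empty(n_perm)
    for p in range(n_perm):
        nulls[p] = metric(labels[rng.permutation(labels.shape[0])])
    if direction == "greater":
        extreme = float(nulls.max())
        count = int(np.sum(nulls >= observed))
    else:
        extreme = float(nulls.min())
        count = int(np.sum(nulls <= observed))
    return {"observed": observed, "null_extreme": extreme,
            "p_value": (1 + count) / (n_perm + 1), "n_perm": n_perm}


# ---------------------------------------------------------------------------
# Consensus representations
# ---------------------------------------------------------------------------


def consensus_by_compound(features: np.ndarray, sample_ids: list[str],
                          metadata: list[SampleMetadata],
                          binarize: bool = False
                          ) -> tuple[list[str], np.ndarray]:
    """Average each compound's replicate rows; optionally threshold at 0.5.

    For barcodes the mean is taken on the hidden activations and then
    thresholded (binarize=True); for z-scores and GSEA profiles the plain
    mean is the consensus.
    """
    meta = {m.sample_id: m for m in metadata}
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(sample_ids):
        groups.setdefault(meta[s].compound_id, []).append(i)
    compound_ids = sorted(groups)
    rows = np.vstack([np.asarray(features)[groups[c]].mean(axis=0)
                      for c in compound_ids])
    if binarize:
        rows = (rows >= 0.5).astype(np.int8)
    return compound_ids, rows
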