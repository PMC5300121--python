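import itertools

import numpy as np
import pytest

from pertbarcode import evaluate as ev
from pertbarcode.evaluate import (DistanceMatrix, adjusted_rand_index,
                                  cluster_expression, consensus_by_compound,
                                  hts_fp_correlation_matrix,
                                  mantel_correlation, permutation_null,
                                  promiscuity_regression,
                                  replicate_rank_summary, shared_target_t)
from pertbarcode.io import CompoundAnnotation, SampleMetadata


def _meta(pairs_of_samples):
    records = []
    for c, samples in enumerate(pairs_of_samples):
        for s in samples:
            records.append(SampleMetadata(s, f"cpd{c}", f"rg{c}", "b0", "PC3"))
    return records


class TestReplicateRank:
    def test_adjacent_replicates_give_median_rank_two(self, rng):
        # replicate pairs tightly co-located, compounds far apart
        centers = rng.normal(0, 50, size=(10, 4))
        features, ids, groups = [], [], []
        for c in range(10):
            for r in range(2):
                features.append(centers[c] + rng.normal(0, 0.01, size=4))
                ids.append(f"c{c}_r{r}")
            groups.append((f"c{c}_r0", f"c{c}_r1"))
        dm = DistanceMatrix.from_features(np.asarray(features), ids)
        median, ranks = replicate_rank_summary(dm, _meta(groups))
        assert median == 2.0
        assert all(r == 2.0 for r in ranks.values())

    def test_hand_ranked_toy_replicate_farthest(self):
        # s0's replicate s1 is farther than the unrelated s2
        ids = ["s0", "s1", "s2"]
        meta = [SampleMetadata("s0", "A", "rgA", "b0", "PC3"),
                SampleMetadata("s1", "A", "rgA", "b1", "PC3"),
                SampleMetadata("s2", "B", "rgB", "b0", "PC3")]
        # condensed order: (s0,s1), (s0,s2), (s1,s2)
        dm = DistanceMatrix(ids, np.array([5.0, 1.0, 2.0]))
        _, ranks = replicate_rank_summary(dm, meta)
        assert ranks["s0"] == 3.0
        assert ranks["s1"] == 3.0

    def test_invariant_under_sample_relabeling(self, rng):
        features = rng.normal(size=(12, 5))
        ids = [f"s{i}" for i in range(12)]
        groups = [(ids[2 * i], ids[2 * i + 1]) for i in range(6)]
        meta = _meta(groups)
        dm = DistanceMatrix.from_features(features, ids)
        median1, _ = replicate_rank_summary(dm, meta)
        perm = rng.permutation(12)
        dm2 = DistanceMatrix.from_features(features[perm],
                                           [ids[i] for i in perm])
        median2, _ = replicate_rank_summary(dm2, meta)
        assert median1 == median2

    def test_no_replicates_is_an_error(self):
        meta = [SampleMetadata(f"s{i}", f"c{i}", f"rg{i}", "b0", "PC3")
                for i in range(3)]
        dm = DistanceMatrix([f"s{i}" for i in range(3)], np.ones(3))
        with pytest.raises(ValueError, match="replicate"):
            replicate_rank_summary(dm, meta)


class TestSharedTargetT:
    def _annotations(self):
        return [CompoundAnnotation("c0", [("T1", 0.1)]),
                CompoundAnnotation("c1", [("T1", 0.5)]),
                CompoundAnnotation("c2", [("T2", 0.2)]),
                CompoundAnnotation("c3", [("T2", 0.3)])]

    def test_identical_constant_groups_give_zero(self):
        dm = DistanceMatrix(["c0", "c1", "c2", "c3"], np.full(6, 3.0))
        assert shared_target_t(dm, self._annotations()) == 0.0

    def test_sharing_pairs_closer_gives_negative_t(self, rng):
        # sharing pairs at distance ~1, non-sharing at ~10
        square = np.full((4, 4), 10.0) + rng.normal(0, 0.1, size=(4, 4))
        square = (square + square.T) / 2
        square[0, 1] = square[1, 0] = 1.0
        square[2, 3] = square[3, 2] = 1.1
        np.fill_diagonal(square, 0.0)
        from scipy.spatial.distance import squareform
        dm = DistanceMatrix(["c0", "c1", "c2", "c3"], squareform(square))
        assert shared_target_t(dm, self._annotations()) < 0

    def test_matches_hand_welch_t(self):
        # sharing distances {1, 2}; non-sharing {4, 5, 6, 7}
        ids = ["c0", "c1", "c2", "c3"]
        # condensed: (01)=1 share, (02)=4, (03)=5, (12)=6, (13)=7, (23)=2 share
        dm = DistanceMatrix(ids, np.array([1.0, 4.0, 5.0, 6.0, 7.0, 2.0]))
        t = shared_target_t(dm, self._annotations())
        a, b = np.array([1.0, 2.0]), np.array([4.0, 5.0, 6.0, 7.0])
        expected = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 2 + b.var(ddof=1) / 4)
        assert t == pytest.approx(expected, abs=1e-12)

    def test_per_target_mean_mode(self, rng):
        # 6 compounds, two targets shared by 3 compounds each -> 3 sharing
        # pairs per target; sharing pairs are systematically closer
        annots = [CompoundAnnotation(f"c{i}", [("T1" if i < 3 else "T2", 0.2)])
                  for i in range(6)]
        ids = [f"c{i}" for i in range(6)]
        square = np.full((6, 6), 10.0) + rng.normal(0, 0.2, size=(6, 6))
        square = (square + square.T) / 2
        for i in range(6):
            for j in range(6):
                if i != j and (i < 3) == (j < 3):
                    square[i, j] = square[j, i] = 2.0 + 0.1 * (i + j)
        np.fill_diagonal(square, 0.0)
        from scipy.spatial.distance import squareform
        dm = DistanceMatrix(ids, squareform(square))
        per_target = shared_target_t(dm, annots, pooled=False)
        pooled = shared_target_t(dm, annots, pooled=True)
        assert per_target < 0 and pooled < 0
        assert per_target != pooled  # different contrasts in general

    def test_potency_cutoff_excludes_weak_annotations(self):
        annots = [CompoundAnnotation("c0", [("T1", 5.0)]),  # too weak
                  CompoundAnnotation("c1", [("T1", 0.5)]),
                  CompoundAnnotation("c2", [("T2", 0.2)]),
                  CompoundAnnotation("c3", [("T2", 0.3)])]
        dm = DistanceMatrix(["c0", "c1", "c2", "c3"],
                            np.array([1.0, 4.0, 5.0, 6.0, 7.0, 2.0]))
        with pytest.raises(ValueError):
            # c0 drops out; only one sharing pair remains -> error
            shared_target_t(dm, annots)


class TestClustering:
    def test_two_blobs_recovered_by_both_methods(self, rng):
        blob_a = rng.normal(0, 0.3, size=(10, 4))
        blob_b = rng.normal(8, 0.3, size=(10, 4))
        X = np.vstack([blob_a, blob_b])
        truth = [0] * 10 + [1] * 10
        for method in ("tree_cut", "clara"):
            labels = cluster_expression(X, method=method, seed=0)
            assert adjusted_rand_index(labels, truth) == 1.0

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 5))
        a = cluster_expression(X, method="clara", seed=3)
        b = cluster_expression(X, method="clara", seed=3)
        np.testing.assert_array_equal(a, b)

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            cluster_expression(np.zeros((2, 3)), min_cluster_size=3)

    def test_tree_cut_respects_minimum_cluster_size(self, rng):
        centers = rng.normal(0, 20, size=(4, 6))
        X = np.vstack([c + rng.normal(0, 0.5, size=(5, 6)) for c in centers])
        labels = cluster_expression(X, method="tree_cut", min_cluster_size=3)
        sizes = np.bincount(labels)
        assert np.all(sizes[sizes > 0] >= 3)


class TestARI:
    def test_identical_partitions_score_one(self):
        assert adjusted_rand_index([0, 0, 1, 1, 2], [5, 5, 9, 9, 7]) == 1.0

    def test_singletons_vs_one_block_scores_zero(self):
        n = 6
        assert adjusted_rand_index(list(range(n)), [0] * n) == 0.0

    def test_matches_pair_counting_oracle(self):
        """Contingency [[2,1],[1,2]]: brute-force agreement over all C(6,2)
        pairs reproduces the adjusted index."""
        labels_a = [0, 0, 0, 1, 1, 1]
        labels_b = [0, 0, 1, 0, 1, 1]

        def brute_force_ari(a, b):
            n = len(a)
            pairs = list(itertools.combinations(range(n), 2))
            n11 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] == b[j])
            n00 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] != b[j])
            n10 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] != b[j])
            n01 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] == b[j])
            index = n11
            expected = (n11 + n10) * (n11 + n01) / len(pairs)
            maximum = ((n11 + n10) + (n11 + n01)) / 2
            return (index - expected) / (maximum - expected)

        assert adjusted_rand_index(labels_a, labels_b) == pytest.approx(
            brute_force_ari(labels_a, labels_b), abs=1e-12)

    def test_random_partition_has_near_zero_expected_ari(self, rng):
        n = 200
        fixed = rng.integers(0, 10, size=n)
        values = [adjusted_rand_index(fixed, rng.integers(0, 10, size=n))
                  for _ in range(100)]
        assert abs(np.mean(values)) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            adjusted_rand_index([0, 1], [0, 1, 2])


class TestMantel:
    def test_identical_and_negated(self, rng):
        X = rng.normal(size=(6, 3))
        dm = DistanceMatrix.from_features(X, [f"s{i}" for i in range(6)])
        assert mantel_correlation(dm, dm) == pytest.approx(1.0)
        assert mantel_correlation(dm.square(), -dm.square()) == pytest.approx(-1.0)

    def test_matches_direct_pearson_on_lower_triangle(self):
        A = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0.0]])
        B = np.array([[0, 2, 1, 7], [2, 0, 3, 2], [1, 3, 0, 5], [7, 2, 5, 0.0]])
        a = [1, 2, 4, 3, 5, 6]
        b = [2, 1, 3, 7, 2, 5]
        expected = np.corrcoef(a, b)[0, 1]
        assert mantel_correlation(A, B) == pytest.approx(expected, abs=1e-12)

    def test_sample_order_mismatch_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        a = DistanceMatrix.from_features(X, ["a", "b", "c", "d"])
        b = DistanceMatrix.from_features(X, ["b", "a", "c", "d"])
        with pytest.raises(ValueError, match="order"):
            mantel_correlation(a, b)


class TestHtsFingerprints:
    def test_identical_fingerprints_correlate_perfectly(self, rng):
        fp = rng.normal(size=10)
        annots = [CompoundAnnotation("a", hts_fingerprint=fp.copy()),
                  CompoundAnnotation("b", hts_fingerprint=fp.copy())]
        ids, corr = hts_fp_correlation_matrix(annots)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_disjoint_assay_coverage_is_missing(self):
        fp_a = np.array([1.0, 2.0, np.nan, np.nan, np.nan, np.nan])
        fp_b = np.array([np.nan, np.nan, 3.0, 1.0, 2.0, 5.0])
        annots = [CompoundAnnotation("a", hts_fingerprint=fp_a),
                  CompoundAnnotation("b", hts_fingerprint=fp_b)]
        _, corr = hts_fp_correlation_matrix(annots)
        assert np.isnan(corr[0, 1])

    def test_clipping_applied_before_correlation(self):
        # an artifactual 25 is clipped to 20, changing the correlation
        raw_a = np.array([1.0, 2.0, 3.0, 25.0])
        raw_b = np.array([2.0, 1.0, 4.0, 10.0])
        annots = [CompoundAnnotation("a", hts_fingerprint=raw_a),
                  CompoundAnnotation("b", hts_fingerprint=raw_b)]
        _, corr = hts_fp_correlation_matrix(annots)
        clipped = np.corrcoef(np.clip(raw_a, -20, 20), raw_b)[0, 1]
        unclipped = np.corrcoef(raw_a, raw_b)[0, 1]
        assert corr[0, 1] == pytest.approx(clipped, abs=1e-12)
        assert corr[0, 1] != pytest.approx(unclipped, abs=1e-6)


class TestPromiscuityRegression:
    def test_noiseless_linear_outcome_is_learnable(self, rng):
        X = rng.normal(size=(80, 5))
        y = 0.2 + 0.1 * X[:, 0] - 0.05 * X[:, 1]
        r2, _ = promiscuity_regression(X, y, seed=0)
        assert r2 > 0.95

    def test_permuted_outcome_is_not_learnable(self, rng):
        X = rng.normal(size=(80, 5))
        y = 0.2 + 0.1 * X[:, 0]
        r2, _ = promiscuity_regression(X, rng.permutation(y), seed=0)
        assert r2 <= 0.05

    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(40, 3))
        y = X[:, 0] + rng.normal(0, 0.5, size=40)
        assert promiscuity_regression(X, y, seed=1) == \
               promiscuity_regression(X, y, seed=1)

    def test_constant_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            promiscuity_regression(rng.normal(size=(40, 3)), np.ones(40))


class TestPermutationNull:
    def test_observed_beyond_all_nulls(self):
        labels = np.array([1] * 10 + [0] * 10)

        def metric(lab):  # label-ordering statistic maximal for the truth
            return float(np.sum(lab[:10]))

        result = permutation_null(metric, labels, n_perm=100, seed=0)
        assert result["p_value"] == pytest.approx(1 / 101)
        assert result["p_value"] < 0.01
        assert result["null_extreme"] < result["observed"]

    def test_observed_at_null_median_has_central_p(self):
        # the observed statistic (first element) sits at the median of the
        # permutation distribution, so p should be near 0.5
        labels = np.array([15] + list(range(15)) + list(range(16, 31)))

        def metric(lab):
            return float(lab[0])

        result = permutation_null(metric, labels, n_perm=200, seed=1)
        assert 0.35 < result["p_value"] < 0.65

    def test_reproducible_from_seed(self, rng):
        labels = rng.normal(size=20)
        metric = lambda lab: float(np.sum(lab[:5]))
        a = permutation_null(metric, labels, n_perm=50, seed=9)
        b = permutation_null(metric, labels, n_perm=50, seed=9)
        assert a == b


def test_consensus_by_compound_means_and_binarizes():
    meta = [SampleMetadata("s0", "A", "rgA", "b0", "PC3"),
            SampleMetadata("s1", "A", "rgA", "b1", "PC3"),
            SampleMetadata("s2", "B", "rgB", "b0", "PC3")]
    feats = np.array([[0.4, 0.9], [0.8, 0.1], [0.2, 0.2]])
    ids, rows = consensus_by_compound(feats, ["s0", "s1", "s2"], meta)
    assert ids == ["A", "B"]
    np.testing.assert_allclose(rows[0], [0.6, 0.5])
    _, bits = consensus_by_compound(feats, ["s0", "s1", "s2"], meta,
                                    binarize=True)
    np.testing.assert_array_equal(bits, [[1, 1], [0, 0]])


def test_metrics_invariant_to_simultaneous_reordering(rng, tiny_dataset):
    ds = tiny_dataset
    features = ds.expression.values.T
    ids = ds.expression.sample_ids
    dm = DistanceMatrix.from_features(features, ids)
    m1, _ = replicate_rank_summary(dm, ds.metadata)
    perm = rng.permutation(len(ids))
    dm2 = DistanceMatrix.from_features(features[perm], [ids[i] for i in perm])
    m2, _ = replicate_rank_summary(dm2, ds.metadata)
    assert m1 == m2
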