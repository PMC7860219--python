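"""Unit and property tests for matrix conditioning and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.cluster.hierarchy import cophenet

from npomics import (
    ValidationError,
    hierarchical_cluster,
    log2_transform,
    median_center,
    quantile_normalize,
)
from npomics.preprocess import QuantileNormalizer

from conftest import make_matrix


class TestLog2Transform:
    def test_exact_power_of_two(self):
        m = make_matrix([[8.0, 8.0, 8.0, 8.0]], scale="linear")
        out = log2_transform(m)
        assert out.scale == "log2"
        assert np.allclose(out.values, 3.0)

    def test_pseudocount_maps_zero_to_zero(self):
        m = make_matrix([[0.0, 0.0]], scale="linear")
        assert np.allclose(log2_transform(m, pseudocount=1.0).values, 0.0)

    def test_round_trip(self, rng):
        m = make_matrix(rng.uniform(0.1, 100, size=(30, 6)), scale="linear")
        assert np.allclose(2.0 ** log2_transform(m).values, m.values)

    def test_nonpositive_error_names_feature_and_sample(self):
        m = make_matrix([[1.0, -2.0]], scale="linear", feature_ids=["badfeat"])
        with pytest.raises(ValidationError, match="badfeat"):
            log2_transform(m)


class TestQuantileNormalize:
    def test_hand_oracle(self):
        # columns (1,2,3) and (4,5,6): rank means are (2.5, 3.5, 4.5)
        m = make_matrix([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]], n_per_group=1)
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.values, expected)

    def test_identical_columns_fixed_point(self, rng):
        col = rng.normal(size=12)
        m = make_matrix(np.column_stack([col] * 4))
        assert np.allclose(quantile_normalize(m).values, m.values)

    def test_sorted_columns_identical_and_idempotent(self, rng):
        m = make_matrix(rng.normal(size=(40, 6)))
        once = quantile_normalize(m)
        sorted_cols = np.sort(once.values, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])
        twice = quantile_normalize(once)
        assert np.allclose(twice.values, once.values)

    def test_ties_get_mean_of_tied_targets(self):
        # reference = (1.5, 2.0, 5.5); column 2 ties at ranks 1-2 -> mean 1.75
        m = make_matrix([[1.0, 2.0], [2.0, 2.0], [3.0, 8.0]], n_per_group=1)
        out = quantile_normalize(m)
        assert np.allclose(out.values[:, 0], [1.5, 2.0, 5.5])
        assert np.allclose(out.values[:, 1], [1.75, 1.75, 5.5])

    def test_single_sample_warns_and_returns_unchanged(self):
        m = make_matrix([[1.0], [2.0]], n_per_group=1)
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)

    def test_sklearn_transformer_maps_new_sample_onto_reference(self, rng):
        X = rng.normal(size=(5, 20))
        qn = QuantileNormalizer().fit(X)
        new = qn.transform(rng.normal(size=(1, 20)))
        assert np.allclose(np.sort(new[0]), qn.reference_)


class TestMedianCenter:
    def test_simple_row(self):
        m = make_matrix([[1.0, 2.0, 3.0, 3.0]])
        out = median_center(m)
        assert np.allclose(out.values[0], [-1.5, -0.5, 0.5, 0.5])

    def test_constant_row_goes_to_zero(self):
        m = make_matrix([[7.0, 7.0, 7.0, 7.0]])
        assert np.allclose(median_center(m).values, 0.0)

    @given(
        arrays(
            np.float64,
            (6, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_row_medians_zero_and_shape_preserved(self, values):
        m = make_matrix(values)
        out = median_center(m)
        assert np.allclose(np.median(out.values, axis=1), 0.0, atol=1e-12)
        # between-sample differences within each row are untouched
        assert np.allclose(np.diff(out.values, axis=1), np.diff(values, axis=1), atol=1e-9)


def brute_force_average_linkage(dist: np.ndarray) -> np.ndarray:
    """O(n^3) agglomeration oracle returning the cophenetic distance matrix."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        (a, b), height = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = height
        merged = clusters.pop(a) + clusters.pop(b)
        new = max(max(clusters, default=-1), a, b) + 1
        nd = {}
        for key in list(d):
            if a in key or b in key:
                del d[key]
        for c, members in clusters.items():
            # unweighted average linkage: mean pairwise distance between members
            total = sum(dist[i, j] for i in merged for j in members)
            nd[(min(c, new), max(c, new))] = total / (len(merged) * len(members))
        clusters[new] = merged
        d.update(nd)
    return coph


class TestHierarchicalCluster:
    def test_identical_features_merge_first_at_zero(self):
        m = make_matrix([[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 3, 0]], feature_ids=list("abc"))
        dendro = hierarchical_cluster(m)
        assert dendro.linkage[0, 2] == pytest.approx(0.0)
        assert set(dendro.linkage[0, :2].astype(int)) == {0, 1}

    def test_matches_brute_force_agglomeration(self, rng):
        from npomics.preprocess import correlation_distance
        from scipy.spatial.distance import squareform

        for _ in range(5):
            m = make_matrix(rng.normal(size=(8, 6)))
            dendro = hierarchical_cluster(m)
            dist = squareform(correlation_distance(m.values))
            expected = brute_force_average_linkage(dist)
            got = squareform(cophenet(dendro.linkage))
            assert np.allclose(got, expected, atol=1e-10)

    def test_leaf_order_is_permutation(self, rng):
        m = make_matrix(rng.normal(size=(12, 6)))
        dendro = hierarchical_cluster(m)
        assert sorted(dendro.leaf_order) == sorted(m.feature_ids)
        assert dendro.n_merges == 11

    def test_merge_heights_nondecreasing(self, rng):
        m = make_matrix(rng.normal(size=(15, 6)))
        heights = hierarchical_cluster(m).linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_row_order_invariance(self, rng):
        values = rng.normal(size=(10, 6))
        m1 = make_matrix(values, feature_ids=[f"g{i}" for i in range(10)])
        perm = rng.permutation(10)
        m2 = make_matrix(values[perm], feature_ids=[f"g{i}" for i in perm])
        c1 = dict(zip(m1.feature_ids, range(10)))
        d1, d2 = hierarchical_cluster(m1), hierarchical_cluster(m2)
        coph1 = squareform_by_label(d1)
        coph2 = squareform_by_label(d2)
        for pair, h in coph1.items():
            assert coph2[pair] == pytest.approx(h)

    def test_zero_variance_item_gets_fallback_distance(self):
        m = make_matrix([[5, 5, 5, 5], [1, 2, 3, 4], [2, 4, 6, 8]])
        with pytest.warns(UserWarning, match="zero-variance"):
            dendro = hierarchical_cluster(m)
        assert dendro.n_merges == 2

    def test_samples_axis(self, rng):
        m = make_matrix(rng.normal(size=(20, 6)))
        dendro = hierarchical_cluster(m, axis="samples")
        assert sorted(dendro.leaf_order) == sorted(m.sample_ids)

    def test_newick_mentions_every_leaf(self, rng):
        m = make_matrix(rng.normal(size=(5, 6)))
        newick = hierarchical_cluster(m).to_newick()
        assert newick.endswith(";")
        for fid in m.feature_ids:
            assert fid in newick


def squareform_by_label(dendro):
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform

    mat = squareform(cophenet(dendro.linkage))
    labels = dendro.labels
    return {
        frozenset((labels[i], labels[j])): mat[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
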