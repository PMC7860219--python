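"""Matrix conditioning: log2 transform, quantile normalization, median
centering, and average-linkage hierarchical clustering under 1 - Pearson r.

The transformers follow the scikit-learn estimator contract (``fit`` /
``transform``, parameters in ``__init__``, fitted state with a trailing
underscore) and operate on arrays of shape (n_samples, n_features), so they
compose with sklearn pipelines. The module-level functions wrap them for
:class:`~npomics.matrix.ExpressionMatrix` inputs, which store features as
rows in the usual omics orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import ValidationError
from .matrix import ExpressionMatrix


class Log2Transformer(TransformerMixin, BaseEstimator):
    """Elementwise ``log2(x + pseudocount)``.

    Raises on values that would go to -inf; the error names the offending
    row and column so bad cells in a signal matrix can be traced.
    """

    def __init__(self, pseudocount: float = 0.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        shifted = X + self.pseudocount
        if (shifted <= 0).any():
            i, j = map(int, np.argwhere(shifted <= 0)[0])
            raise ValidationError(
                f"non-positive value at row {i}, column {j} cannot be log2-transformed "
                f"with pseudocount {self.pseudocount}"
            )
        return np.log2(shifted)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every sample onto a common reference distribution.

    ``fit`` records the reference (the mean across samples of the sorted
    per-sample values); ``transform`` replaces each sample's values by the
    reference value of their rank, tied values receiving the mean of the
    reference values over their tied ranks. With a single sample the input
    is returned unchanged with a warning.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        out = np.empty_like(X, dtype=float)
        for s in range(X.shape[0]):
            out[s] = _map_to_reference(X[s], self.reference_)
        return out


def _map_to_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Assign reference[rank] per value; ties get the mean over tied ranks."""
    order = np.argsort(values, kind="stable")
    assigned = np.empty_like(reference, dtype=float)
    assigned[order] = reference
    # average the assigned targets within each group of tied input values
    uniq, inverse = np.unique(values, return_inverse=True)
    sums = np.bincount(inverse, weights=assigned, minlength=len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    return (sums / counts)[inverse]


class MedianCenterer(TransformerMixin, BaseEstimator):
    """Subtract each feature's median across samples (columns of X)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.medians_ = np.median(X, axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return X - self.medians_


# ---------------------------------------------------------------------------
# ExpressionMatrix-facing wrappers (features x samples orientation)
# ---------------------------------------------------------------------------


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Return the matrix on the log2 scale. Input must be linear-scale."""
    if matrix.scale != "linear":
        raise ValidationError("log2_transform expects a linear-scale matrix")
    shifted = matrix.data.to_numpy(dtype=float) + pseudocount
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if (shifted <= 0).any():
        i, j = map(int, np.argwhere(shifted <= 0)[0])
        raise ValidationError(
            f"non-positive value for feature {matrix.data.index[i]!r}, "
            f"sample {matrix.data.columns[j]!r} cannot be log2-transformed"
        )
    out = pd.DataFrame(np.log2(shifted), index=matrix.data.index, columns=matrix.data.columns)
    return matrix.with_data(out, scale="log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so their value distributions coincide."""
    matrix.check_finite()
    if matrix.data.shape[1] == 1:
        warnings.warn("single-sample matrix returned unchanged", stacklevel=2)
        return matrix.with_data(matrix.data.copy())
    X = matrix.data.to_numpy(dtype=float).T  # samples x features
    qn = QuantileNormalizer().fit(X)
    out = pd.DataFrame(
        qn.transform(X).T, index=matrix.data.index, columns=matrix.data.columns
    )
    return matrix.with_data(out)


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's median; expects log2-scale input."""
    if matrix.scale != "log2":
        raise ValidationError("median_center expects a log2-scale matrix")
    data = matrix.data
    out = data.sub(data.median(axis=1), axis=0)
    return matrix.with_data(out)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Average-linkage merge tree over items (features or samples).

    ``linkage`` is a scipy linkage matrix: each row (a, b, height, size)
    merges clusters a and b. ``labels`` are the item ids in input order and
    ``leaf_order`` the ids left-to-right under the tree.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_merges(self) -> int:
        return self.linkage.shape[0]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(tree, tree.dist) + ";"


def correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distances between rows.

    Zero-variance rows have undefined correlation; their distances fall back
    to 1 (with a warning), keeping the matrix well defined.
    """
    sd = profiles.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance item(s); using fallback distance 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "features") -> Dendrogram:
    """Average-linkage agglomeration under d = 1 - Pearson r."""
    if axis not in ("features", "samples"):
        raise ValidationError(f"axis must be 'features' or 'samples', got {axis!r}")
    profiles = matrix.data.to_numpy(dtype=float)
    labels = matrix.feature_ids
    if axis == "samples":
        profiles = profiles.T
        labels = matrix.sample_ids
    if profiles.shape[0] < 2:
        raise ValidationError("need at least 2 items to cluster")
    Z = hierarchy.linkage(correlation_distance(profiles), method="average")
    return Dendrogram(linkage=Z, labels=list(labels))
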