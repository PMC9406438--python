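"""PCA on the integration table and k-means clustering of PC scores.

Patients are embedded in the space of the first ten principal components of
the (standardized) integration table and partitioned by k-means with
k-means++ initialization; cluster quality is summarized by the average
silhouette coefficient computed in the same score space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.utils.validation import check_is_fitted

from omicsurv.exceptions import ValidationError
from omicsurv.reduction import IntegrationTable


@dataclass
class PCAModel:
    """Fitted PCA: loadings (features x PCs), scores (samples x PCs),
    explained-variance fractions. Component signs are fixed so each loading
    column's largest-magnitude element is positive."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    n_components: int


@dataclass
class ClusterAssignment:
    """Per-sample 1-based cluster labels with silhouette summary.

    Labels are renumbered so cluster 1 is the largest cluster.
    """

    labels: pd.Series
    silhouette_values: np.ndarray
    silhouette_avg: float
    k: int
    seed: int | None


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, IntegrationTable):
        return table.data
    if isinstance(table, pd.DataFrame):
        return table
    arr = np.asarray(table, dtype=float)
    return pd.DataFrame(arr)


class PCScoreClusterer(BaseEstimator, ClusterMixin):
    """PCA + k-means estimator over an integration table.

    Fits a centered PCA with ``n_components`` components, fixes component
    signs deterministically, then runs k-means (k-means++ init, ``n_init``
    restarts, best inertia kept) on the score matrix. Labels are 1-based
    and renumbered so cluster 1 is the largest.

    Attributes
    ----------
    pca_model_ : PCAModel
    labels_ : ndarray, 1-based cluster labels
    silhouette_avg_ : float
    silhouette_values_ : ndarray
    explained_variance_ratio_ : ndarray
    """

    def __init__(
        self,
        n_components: int = 10,
        n_clusters: int = 2,
        n_init: int = 25,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        frame = _as_frame(X)
        model = fit_pca(frame, n_components=self.n_components)
        assignment = cluster_scores(
            model, k=self.n_clusters, seed=self.random_state, n_init=self.n_init
        )
        self.pca_model_ = model
        self.assignment_ = assignment
        self.labels_ = assignment.labels.to_numpy()
        self.scores_ = model.scores
        self.loadings_ = model.loadings
        self.explained_variance_ratio_ = model.explained_variance_ratio
        self.silhouette_avg_ = assignment.silhouette_avg
        self.silhouette_values_ = assignment.silhouette_values
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def silhouette_scan(self, X, k_range=range(2, 7)) -> pd.Series:
        """Average silhouette over a range of k (diagnostic for choosing k)."""
        frame = _as_frame(X)
        model = fit_pca(frame, n_components=self.n_components)
        out = {}
        for k in k_range:
            if k >= len(frame):
                break
            out[k] = cluster_scores(
                model, k=k, seed=self.random_state, n_init=self.n_init
            ).silhouette_avg
        return pd.Series(out, name="silhouette")


def fit_pca(table, n_components: int = 10) -> PCAModel:
    """Centered PCA of the integration table, deterministic up to fixed signs.

    ``n_components`` exceeding the achievable rank is reduced with a
    warning. Input is assumed already standardized upstream (the PCA itself
    only centers).
    """
    frame = _as_frame(table)
    n, p = frame.shape
    max_comp = min(n - 1, p)
    if max_comp < 1:
        raise ValidationError("fit_pca: need at least 2 samples and 1 feature")
    if n_components > max_comp:
        warnings.warn(
            f"fit_pca: n_components reduced from {n_components} to rank bound {max_comp}",
            stacklevel=2,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(frame.to_numpy())
    loadings = pca.components_.T  # features x components, unit-norm columns

    # sign convention: largest-|loading| element of each column made positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[None, :]
    scores = scores * flip[None, :]

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=frame.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=frame.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=n_components,
    )


def cluster_scores(
    model: PCAModel, k: int = 2, seed: int | None = None, n_init: int = 25
) -> ClusterAssignment:
    """k-means (k-means++ init) on PC scores with silhouette assessment.

    The silhouette is computed with Euclidean distance in the clustering
    (score) space. Labels are renumbered by decreasing cluster size.
    """
    scores = model.scores.to_numpy()
    n = scores.shape[0]
    if k < 2:
        raise ValidationError("cluster_scores: k must be at least 2")
    if k > n:
        raise ValidationError(f"cluster_scores: k={k} exceeds n_samples={n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(scores)

    # renumber: cluster 1 = largest (ties broken by original label order)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=model.scores.index, name="cluster")

    if len(set(raw)) > 1:
        sil = silhouette_samples(scores, raw)
    else:  # degenerate k-means outcome
        sil = np.zeros(n)
    return ClusterAssignment(
        labels=labels,
        silhouette_values=sil,
        silhouette_avg=float(sil.mean()),
        k=k,
        seed=seed,
    )
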