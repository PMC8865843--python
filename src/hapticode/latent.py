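"""Latent-space analyses: PCA, material embeddings, distance matrices, t-SNE.

The autoencoder's codes are redundant; a PCA retaining 95% of their variance
defines the *latent PCs space* in which all downstream analyses run. Each
material is embedded as the mean projection of its segments, categories get
centroids, and pairwise Euclidean centroid distances form a category
distance matrix directly comparable (via Pearson correlation over the 21
unique category pairs) with the perceptual distance matrix from the rating
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "DistanceMatrix",
    "LatentPCA",
    "fit_latent_pca",
    "material_embeddings",
    "category_centroids",
    "centroid_distance_matrix",
    "tsne_embed",
    "matrix_correlation",
]


@dataclass
class DistanceMatrix:
    """Symmetric category-by-category dissimilarities with a flavor tag."""

    labels: list
    values: np.ndarray
    flavor: str = "latent_centroid"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix must be square with one row per label")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n_pairs(self) -> int:
        k = len(self.labels)
        return k * (k - 1) // 2

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


class LatentPCA(TransformerMixin, BaseEstimator):
    """PCA over latent codes, retaining the top components that reach a
    cumulative explained-variance threshold (default 95%).

    Attributes
    ----------
    k_ : retained dimensionality (smallest k whose cumulative explained
        variance reaches the threshold).
    explained_variance_ratio_ : ratios for *all* components (sum to 1).
    projections_ : centered projections of the fitted codes, (N, k_).
    """

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must be in (0, 1]")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] <= X.shape[1]:
            raise ValueError("need more code vectors than latent dimensions")
        self.pca_ = PCA(n_components=None, svd_solver="full").fit(X)
        ratios = self.pca_.explained_variance_ratio_
        cum = np.cumsum(ratios)
        self.k_ = int(np.searchsorted(cum, self.variance_threshold - 1e-12) + 1)
        self.k_ = min(self.k_, len(ratios))
        self.explained_variance_ratio_ = ratios
        self.components_ = self.pca_.components_[: self.k_]
        self.projections_ = self.pca_.transform(X)[:, : self.k_]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return self.pca_.transform(X)[:, : self.k_]

    def inverse_transform_full(self, X_full) -> np.ndarray:
        """Reconstruct codes from all-component projections (lossless)."""
        return self.pca_.inverse_transform(X_full)


def fit_latent_pca(codes, variance_threshold: float = 0.95) -> LatentPCA:
    """Fit the latent PCs space on the full dataset's codes."""
    return LatentPCA(variance_threshold=variance_threshold).fit(codes)


def material_embeddings(pcspace: LatentPCA, metadata: pd.DataFrame, materials=None):
    """Average the projected segments of each material into one point.

    Returns ``(embeddings, labels)``: a materials x k DataFrame (indexed and
    sorted by material_id) and the aligned category labels.
    """
    proj = pcspace.projections_
    if len(metadata) != proj.shape[0]:
        raise ValueError("metadata rows must match the codes the PCA was fit on")
    df = pd.DataFrame(proj, columns=[f"pc{i + 1}" for i in range(proj.shape[1])])
    df["material_id"] = metadata["material_id"].values
    emb = df.groupby("material_id").mean().sort_index()
    if materials is not None:
        missing = sorted(set(materials) - set(emb.index))
        if missing:
            raise ValueError(f"materials without segments: {missing}")
        emb = emb.reindex(sorted(materials))
    labels = (
        metadata.drop_duplicates("material_id")
        .set_index("material_id")["category_id"]
        .reindex(emb.index)
    )
    return emb, labels


def category_centroids(embeddings: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Category centroids: mean embedding across the materials of a category."""
    labels = pd.Series(labels, index=embeddings.index)
    return embeddings.groupby(labels).mean().sort_index()


def centroid_distance_matrix(centroids: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between category centroids."""
    values = squareform(pdist(centroids.values, metric="euclidean"))
    return DistanceMatrix(labels=list(centroids.index), values=values, flavor="latent_centroid")


def tsne_embed(embeddings: pd.DataFrame, seed: int = 0, perplexity: float = 10.0) -> pd.DataFrame:
    """2-D t-SNE view of the material embeddings (visualization aid only)."""
    n = len(embeddings)
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be below the number of materials ({n})")
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(embeddings.values)
    return pd.DataFrame(coords, index=embeddings.index, columns=["tsne1", "tsne2"])


def matrix_correlation(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Pearson r between two distance matrices over their unique upper-triangle
    pairs (21 pairs for 7 categories)."""
    if list(a.labels) != list(b.labels):
        raise ValueError(f"category labels differ: {a.labels} vs {b.labels}")
    return float(pearsonr(a.upper_triangle(), b.upper_triangle())[0])
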