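"""Unsupervised exploration statistics for the report.

Distinct-miRNA counts per sample, top-k feature selection by coefficient of
variation, unit-variance scaling with complete-linkage Euclidean
clustering for heatmaps, and PCA / t-SNE ordination of samples on
log2(RPM + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)


def distinct_counts(raw: pd.DataFrame,
                    thresholds: Sequence[int] = (0, 10)) -> pd.DataFrame:
    """Per-sample number of features with count strictly above each threshold."""
    if (raw.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return pd.DataFrame(
        {f"above_{t}": (raw > t).sum(axis=0) for t in thresholds}
    )


def top_cv_features(rpm: pd.DataFrame, k: int = 50) -> pd.Series:
    """Top-k features by coefficient of variation of RPM across samples.

    CV = sd / mean with the n−1 sample standard deviation; features with
    zero mean are excluded; descending CV, ties broken by feature id.
    Returns a Series (feature → CV) of length ≤ k in rank order.
    """
    mean = rpm.mean(axis=1)
    sd = rpm.std(axis=1, ddof=1)
    cv = (sd / mean)[mean > 0].dropna()
    frame = cv.rename("cv").reset_index()
    frame = frame.sort_values(["cv", "index"], ascending=[False, True],
                              kind="stable")
    top = frame.head(k)
    return pd.Series(top["cv"].to_numpy(), index=top["index"].to_numpy(),
                     name="cv")


def unit_variance_scale(mat: pd.DataFrame) -> pd.DataFrame:
    """Row-wise centering and unit-variance scaling (sd with n−1).

    Constant rows scale to all zeros rather than NaN.
    """
    centered = mat.sub(mat.mean(axis=1), axis=0)
    sd = mat.std(axis=1, ddof=1)
    scaled = centered.div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return scaled


@dataclass
class ClusteredMatrix:
    scaled: pd.DataFrame
    feature_order: list[str]
    sample_order: list[str]
    feature_linkage: Optional[np.ndarray]
    sample_linkage: Optional[np.ndarray]


def scale_and_cluster(rpm: pd.DataFrame,
                      features: Sequence[str]) -> ClusteredMatrix:
    """Unit-variance scale a feature subset and cluster rows and columns.

    Complete-linkage agglomerative clustering on Euclidean distances,
    separately for features and samples. With a single sample (or feature)
    the corresponding clustering is skipped with a warning.
    """
    features = list(features)
    if not features:
        raise ValueError("scale_and_cluster requires a non-empty feature subset")
    scaled = unit_variance_scale(rpm.loc[features])

    def _order(frame: pd.DataFrame, axis_name: str):
        labels = list(frame.index)
        if len(labels) < 2:
            logger.warning("clustering skipped: single %s", axis_name)
            return labels, None
        Z = hierarchy.linkage(frame.to_numpy(), method="complete",
                              metric="euclidean")
        return [labels[i] for i in hierarchy.leaves_list(Z)], Z

    feature_order, fz = _order(scaled, "feature")
    sample_order, sz = _order(scaled.T, "sample")
    return ClusteredMatrix(scaled, feature_order, sample_order, fz, sz)


@dataclass
class Ordination:
    pca_scores: Optional[pd.DataFrame]
    explained_variance_ratio: Optional[np.ndarray]
    tsne: Optional[pd.DataFrame]
    seed: int
    perplexity: Optional[float]


def ordination(rpm: pd.DataFrame, seed: int = 0,
               n_components: int = 2) -> Ordination:
    """PCA and t-SNE of samples on log2(RPM + 1).

    PCA is the eigendecomposition of the sample covariance of the
    feature-centered matrix; component signs are fixed so the
    largest-magnitude loading is positive. Needs ≥ 3 samples; t-SNE needs
    ≥ 4 and runs at perplexity ``min(5, (n − 1) / 3)`` with the recorded
    seed. Skipped sections come back as ``None`` with a warning.
    """
    n = rpm.shape[1]
    x = np.log2(rpm.fillna(0.0).to_numpy(dtype=float).T + 1.0)  # samples × features
    pca_scores = evr = tsne_coords = None
    perplexity = None
    if n >= 3:
        centered = x - x.mean(axis=0, keepdims=True)
        # SVD route to the covariance eigendecomposition
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        ncomp = min(n_components, len(s))
        for j in range(ncomp):
            load = Vt[j]
            if load[np.argmax(np.abs(load))] < 0:
                Vt[j] = -load
                U[:, j] = -U[:, j]
        scores = U[:, :ncomp] * s[:ncomp]
        total_var = (s ** 2).sum()
        evr = (s[:ncomp] ** 2) / total_var if total_var > 0 else np.zeros(ncomp)
        pca_scores = pd.DataFrame(
            scores, index=rpm.columns,
            columns=[f"PC{j + 1}" for j in range(ncomp)],
        )
    else:
        logger.warning("PCA skipped: %d sample(s) < 3", n)
    if n >= 4:
        perplexity = min(5.0, (n - 1) / 3.0)
        emb = TSNE(
            n_components=2, perplexity=perplexity, init="random",
            random_state=seed,
        ).fit_transform(x)
        tsne_coords = pd.DataFrame(emb, index=rpm.columns,
                                   columns=["tSNE1", "tSNE2"])
    else:
        logger.warning("t-SNE skipped: %d sample(s) < 4", n)
    return Ordination(pca_scores, evr, tsne_coords, seed, perplexity)


@dataclass
class ExplorationBundle:
    """Everything the report's data-exploration section needs."""

    distinct: pd.DataFrame
    top_cv: pd.Series
    heatmap_top: ClusteredMatrix
    heatmap_all_detected: Optional[ClusteredMatrix]
    ordination: Ordination


def explore_matrix(raw: pd.DataFrame, rpm: pd.DataFrame, seed: int = 0,
                   k: int = 50) -> ExplorationBundle:
    """Assemble the full exploration bundle from a count matrix.

    The first heatmap uses the top-k CV features; the second uses the
    features detected (count > 0) in every sample, when any exist.
    """
    top = top_cv_features(rpm, k=k)
    everywhere = raw.index[(raw > 0).all(axis=1)]
    return ExplorationBundle(
        distinct=distinct_counts(raw),
        top_cv=top,
        heatmap_top=scale_and_cluster(rpm, list(top.index)),
        heatmap_all_detected=(
            scale_and_cluster(rpm, list(everywhere)) if len(everywhere) else None
        ),
        ordination=ordination(rpm, seed=seed),
    )
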