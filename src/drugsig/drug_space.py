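"""Molecular classification of drugs from their expression profiles.

Drugs are embedded as rows of a profile matrix (log2 fold changes of a
selected transcript set across the time-course), then classified two
ways: agglomerative hierarchical clustering (Euclidean distance,
complete linkage) rendered as a dendrogram/Newick tree, and PCA with
three components, drugs as observations.  Each transcript can then be
correlated with the retained components to see which axis of drug
space it follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .scoring import FoldChangeTable, drug_response_summary


def build_drug_profiles(fct: FoldChangeTable, transcripts) -> pd.DataFrame:
    """Drugs × (transcript, time) matrix of signed log2 fold changes.

    Column order is deterministic: transcript-major in the given order,
    time-minor ascending.
    """
    transcripts = pd.Index(transcripts)
    unknown = transcripts.difference(fct.probes)
    if len(unknown):
        raise KeyError(f"unknown transcript ids: {list(unknown[:5])}")
    wide = fct.per_cell["log2fc"].unstack(["probe_id", "time_h"])
    cols = pd.MultiIndex.from_product(
        [transcripts, fct.time_points], names=["probe_id", "time_h"]
    )
    return wide.reindex(columns=cols)


def cluster_drugs(profiles: pd.DataFrame, method: str = "complete"):
    """Agglomerative dendrogram of drugs (Euclidean distance).

    Returns the scipy linkage matrix; labels follow ``profiles.index``.
    Equal-distance merges are resolved by scipy's stable ordering, so
    the result is deterministic for a fixed row order.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 drugs to cluster")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain NaN/inf")
    return hierarchy.linkage(pdist(X, metric="euclidean"), method=method)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string.

    Branch lengths are differences of merge heights, the convention for
    ultrametric dendrograms.
    """
    labels = list(labels)
    n = len(labels)
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:g}"

    inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)})"
    return inner + ";"


@dataclass
class PCAResult:
    """Principal components of the drug profile matrix.

    ``scores``: drug × component coordinates; ``loadings``: feature ×
    component weights; ``explained_variance_ratio``: fraction of total
    variance per component.  Component signs are fixed so the feature
    with the largest |loading| is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: pd.Series
    column_means: pd.Series

    def reconstruct(self) -> pd.DataFrame:
        approx = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(
            approx + self.column_means.to_numpy(),
            index=self.scores.index,
            columns=self.loadings.index,
        )


def pca_drugs(profiles: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """PCA of column-centered (unscaled) drug profiles, drugs as observations."""
    X = profiles.to_numpy(dtype=float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_comp}")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| feature positive per component
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    total_var = (s**2).sum()
    ratio = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    comps = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(
            U[:, :n_components] * s[:n_components], index=profiles.index, columns=comps
        ),
        loadings=pd.DataFrame(Vt[:n_components].T, index=profiles.columns, columns=comps),
        explained_variance_ratio=pd.Series(ratio[:n_components], index=comps),
        column_means=pd.Series(mu, index=profiles.columns),
    )


def correlate_components(
    pca: PCAResult, fct: FoldChangeTable, transcripts
) -> pd.DataFrame:
    """Pearson correlation of each transcript's drug response with each PC.

    The per-drug transcript summary is the signed log2fc at the time of
    maximum |log2fc|.  Transcripts with zero variance across drugs get
    NaN (undefined correlation).
    """
    summary = drug_response_summary(fct).reindex(index=pd.Index(transcripts))
    summary = summary.loc[:, pca.scores.index]  # align drug order
    X = summary.to_numpy(dtype=float)
    S = pca.scores.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Sc = S - S.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1, keepdims=True)
    sn = np.linalg.norm(Sc, axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc @ Sc) / (xn * sn)
    corr[xn[:, 0] == 0, :] = np.nan
    return pd.DataFrame(corr, index=summary.index, columns=pca.scores.columns)
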