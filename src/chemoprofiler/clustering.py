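"""Candidate-interactor discovery from dose-response competition profiles.

Significance filtering, feature standardization, t-SNE embedding, k-means
clustering, per-cluster compactness, automated sensitive-cluster selection
and annotation-based candidate extraction.  The stage is a pure function of
(matrix, p_matrix, annotation, config): fixed seeds give identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

__all__ = [
    "ClusteringConfig",
    "ClusterAssignment",
    "CandidateReport",
    "significance_filter",
    "standardize_features",
    "tsne_perplexity",
    "embed_tsne",
    "cluster_kmeans",
    "cluster_compactness",
    "select_sensitive_clusters",
    "identify_candidates",
    "run_clustering",
]


@dataclass(frozen=True)
class ClusteringConfig:
    alpha: float = 0.05
    n_clusters: int = 5
    max_perplexity: float = 30.0
    embed_dims: int = 2
    tsne_seed: int = 0
    kmeans_seed: int = 0
    #: centroid log2FC at the top dose must be at or below this to call a
    #: cluster dose-sensitive
    sensitivity_log2fc_cut: float = -1.0
    #: slack allowed when requiring centroid log2FC non-increasing in dose
    monotone_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.max_perplexity <= 0:
            raise ValueError("max_perplexity must be positive")


@dataclass
class ClusterAssignment:
    protein_ids: list[str]
    embedding: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) ints, relabeled by descending cluster size
    compactness: dict[int, float]  # mean pairwise distance per cluster
    sensitive: list[int] = field(default_factory=list)

    def members(self, cluster: int) -> list[str]:
        return [p for p, l in zip(self.protein_ids, self.labels) if l == cluster]


@dataclass
class CandidateReport:
    """Unannotated proteins in dose-sensitive clusters, plus the annotated
    members recovered alongside them (positive controls)."""

    candidates: pd.DataFrame  # protein_id, cluster, compactness, per-dose log2FC
    known_members: pd.DataFrame
    sensitive_clusters: list[int]


def significance_filter(
    matrix: pd.DataFrame, p_matrix: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep rows significant (p < alpha, strict) in at least one condition,
    then drop rows with any missing feature."""
    if not matrix.index.equals(p_matrix.index) or list(matrix.columns) != list(p_matrix.columns):
        raise ValueError("feature and p-value matrices are not aligned")
    sig = (p_matrix < alpha).any(axis=1)
    kept = matrix[sig]
    return kept.dropna(axis=0, how="any")


def standardize_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Columns to zero mean, unit (population) variance; a zero-variance
    column becomes all zeros with a warning."""
    if len(matrix) < 2:
        raise ValueError("standardization needs at least 2 rows")
    if matrix.isna().any().any():
        raise ValueError("missing values must be removed before standardization")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)  # population sd
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance feature column(s): {list(matrix.columns[flat])}", stacklevel=2
        )
    sd_safe = np.where(flat, 1.0, sd)
    out = (vals - mean) / sd_safe
    out[:, flat] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def tsne_perplexity(n: int, max_perplexity: float = 30.0) -> float:
    """Dataset-size-adjusted perplexity: min(max, max(5, floor((n-1)/3))),
    clamped below n as t-SNE requires."""
    p = min(max_perplexity, max(5.0, float((n - 1) // 3)))
    return min(p, float(n - 1))


def embed_tsne(matrix: pd.DataFrame, config: ClusteringConfig = ClusteringConfig()) -> np.ndarray:
    """2-D t-SNE embedding, deterministic under ``tsne_seed`` (PCA init)."""
    n = len(matrix)
    if n < 4:
        raise ValueError("t-SNE embedding needs at least 4 rows")
    tsne = TSNE(
        n_components=config.embed_dims,
        perplexity=tsne_perplexity(n, config.max_perplexity),
        init="pca",
        learning_rate="auto",
        random_state=config.tsne_seed,
    )
    return tsne.fit_transform(matrix.to_numpy(dtype=float))


def cluster_kmeans(
    embedding: np.ndarray, config: ClusteringConfig = ClusteringConfig(), n_clusters: int | None = None
) -> np.ndarray:
    """k-means labels on the embedding, k-means++ with 10 restarts under
    ``kmeans_seed``; clusters relabeled by descending size (ties by first
    occurrence) for stable reporting."""
    k = config.n_clusters if n_clusters is None else n_clusters
    if len(embedding) < k:
        raise ValueError(f"need at least {k} points for k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=config.kmeans_seed)
    raw = km.fit_predict(embedding)
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[l] for l in raw], dtype=int)


def cluster_compactness(embedding: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Mean pairwise Euclidean distance within each cluster; singletons 0.
    Lower values mean tighter clusters."""
    out: dict[int, float] = {}
    for c in sorted(set(int(l) for l in labels)):
        pts = embedding[labels == c]
        out[c] = float(pdist(pts).mean()) if len(pts) >= 2 else 0.0
    return out


def select_sensitive_clusters(
    labels: np.ndarray,
    matrix: pd.DataFrame,
    config: ClusteringConfig = ClusteringConfig(),
) -> list[int]:
    """Clusters whose centroid dose-response is dose-dependently competed:
    mean log2FC at the highest dose <= ``sensitivity_log2fc_cut`` and
    non-increasing across the dose order (within ``monotone_tolerance``)."""
    sensitive = []
    vals = matrix.to_numpy(dtype=float)
    for c in sorted(set(int(l) for l in labels)):
        centroid = vals[labels == c].mean(axis=0)
        if centroid[-1] > config.sensitivity_log2fc_cut:
            continue
        if np.all(np.diff(centroid) <= config.monotone_tolerance):
            sensitive.append(c)
    return sensitive


def identify_candidates(
    assignment: ClusterAssignment,
    matrix: pd.DataFrame,
    annotation: dict[str, str],
) -> CandidateReport:
    """Split sensitive-cluster proteins into unannotated candidates and
    annotated complex members (positive controls)."""
    cand_rows, known_rows = [], []
    for c in assignment.sensitive:
        for pid in assignment.members(c):
            row = {
                "protein_id": pid,
                "cluster": c,
                "compactness": assignment.compactness[c],
                **{f"log2fc_{col}": matrix.at[pid, col] for col in matrix.columns},
            }
            if pid in annotation:
                known_rows.append({**row, "complex": annotation[pid]})
            else:
                cand_rows.append(row)
    cols = ["protein_id", "cluster", "compactness"] + [f"log2fc_{c}" for c in matrix.columns]
    return CandidateReport(
        candidates=pd.DataFrame(cand_rows, columns=cols),
        known_members=pd.DataFrame(known_rows, columns=cols + ["complex"]),
        sensitive_clusters=list(assignment.sensitive),
    )


def run_clustering(
    matrix: pd.DataFrame,
    p_matrix: pd.DataFrame,
    annotation: dict[str, str] | None = None,
    config: ClusteringConfig = ClusteringConfig(),
) -> tuple[ClusterAssignment, CandidateReport]:
    """Full stage: filter -> standardize -> embed -> cluster -> compactness
    -> sensitivity -> candidates."""
    filtered = significance_filter(matrix, p_matrix, config.alpha)
    features = standardize_features(filtered)
    embedding = embed_tsne(features, config)
    labels = cluster_kmeans(embedding, config)
    compact = cluster_compactness(embedding, labels)
    sensitive = select_sensitive_clusters(labels, filtered, config)
    assignment = ClusterAssignment(
        protein_ids=list(features.index),
        embedding=embedding,
        labels=labels,
        compactness=compact,
        sensitive=sensitive,
    )
    report = identify_candidates(assignment, filtered, annotation or {})
    return assignment, report
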