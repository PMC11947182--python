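"""Unsupervised pixel segmentation into tissue regions.

Each sample is segmented independently from its annotated-lipid intensities:
log(1+x) transform, per-feature standardization, PCA, a k-nearest-neighbour
graph reweighted by shared-neighbour (Jaccard) overlap, and modularity-based
community detection with a resolution parameter (0.9 by default).  The
reconstructed defaults (k = 20, Jaccard prune 1/15, 10 principal components)
follow the conventions of the single-cell clustering toolkits this approach
is borrowed from.  Cluster labels are then mapped to morphological lung
regions through a manually curated cluster-to-region map, standing in for
H&E-guided assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .annotate import LipidAnnotation
from .peaks import FeatureMatrix

logger = logging.getLogger("msiregion")

#: Region vocabulary for cluster-to-region maps.
REGION_VOCABULARY = frozenset(
    {
        "airway_epithelium",
        "airway_lumen",
        "basement_membrane",
        "distal_airway_epithelium",
        "alveolar_epithelium",
        "off_tissue",
        "unassigned",
    }
)
#: Regions excluded from group statistics.
NON_STATISTICAL_REGIONS = frozenset({"off_tissue", "unassigned"})


@dataclass
class SegmentationResult:
    """Per-pixel cluster labels for one sample.

    Labels are contiguous integers from 1, ordered by decreasing cluster
    size, and deterministic given (input, seed).
    """

    sample_id: str
    labels: np.ndarray  # (n_pixels,) int, 1-based
    parameters: dict
    cluster_sizes: dict[int, int] = field(default_factory=dict)
    singleton_clusters: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if uniq.size and not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("cluster labels must be contiguous integers from 1")
        if not self.cluster_sizes:
            self.cluster_sizes = {
                int(c): int((self.labels == c).sum()) for c in uniq
            }

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


def preprocess_for_clustering(
    matrix: FeatureMatrix, pca_dims: int = 10
) -> np.ndarray:
    """log1p -> per-feature z-score (clipped at +/-10) -> PCA embedding.

    Zero-variance features are dropped with a warning; the projection keeps
    ``min(pca_dims, retained_features - 1)`` components.
    """
    X = np.log1p(matrix.values)
    std = X.std(axis=0)
    # relative threshold: a numerically constant column has std ~ eps * |x|
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    keep = std > 1e-10 * scale
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} zero-variance feature(s)", stacklevel=2)
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features with non-zero variance")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    X = np.clip(X, -10, 10)
    n_comp = min(pca_dims, X.shape[1] - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    return pca.fit_transform(X)


def build_snn_graph(
    embedding: np.ndarray, k: int = 20, prune: float = 1 / 15
) -> sparse.csr_matrix:
    """Shared-nearest-neighbour graph over pixels.

    Euclidean k-nearest neighbour sets (self included); the edge weight
    between two pixels is the Jaccard overlap of their neighbour sets, and
    edges below ``prune`` are removed.  Returned as a symmetric sparse
    weighted adjacency matrix.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = embedding.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of pixels")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)  # self is its own nearest neighbour
    rows = np.repeat(np.arange(n), k)
    incidence = sparse.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = incidence @ incidence.T  # |A & B|
    shared = shared.tocoo()
    union = 2 * k - shared.data  # |A | B| for equal-size sets
    jaccard = shared.data / union
    keep = (jaccard >= prune) & (shared.row != shared.col)
    adj = sparse.csr_matrix(
        (jaccard[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    return adj


def cluster_pixels(
    graph: sparse.csr_matrix,
    resolution: float = 0.9,
    seed: int = 0,
    sample_id: str = "",
    parameters: Optional[dict] = None,
) -> SegmentationResult:
    """Modularity community detection on the SNN graph (Leiden backend).

    Uses the resolution-parametrized modularity (RBConfiguration) objective;
    labels are relabeled by decreasing cluster size starting at 1.  Isolated
    pixels end up in singleton clusters, which are flagged for review.
    """
    import igraph as ig
    import leidenalg

    n = graph.shape[0]
    if n == 0:
        raise ValueError("graph is empty")
    coo = sparse.triu(graph.tocoo(), k=1)
    g = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist() if coo.data.size else None,
        resolution_parameter=resolution,
        seed=int(seed),
    )
    membership = np.asarray(partition.membership)

    # relabel by decreasing size, 1-based
    ids, counts = np.unique(membership, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[int(m)] for m in membership], dtype=np.int64)
    sizes = {remap[int(i)]: int(c) for i, c in zip(ids, counts)}
    singletons = sorted(c for c, s in sizes.items() if s == 1)
    if singletons:
        logger.info("clustering produced %d singleton cluster(s)", len(singletons))
    params = {"resolution": resolution, "seed": int(seed)}
    if parameters:
        params.update(parameters)
    return SegmentationResult(
        sample_id=sample_id,
        labels=labels,
        parameters=params,
        singleton_clusters=singletons,
    )


def segment_sample(
    matrix: FeatureMatrix,
    k: int = 20,
    prune: float = 1 / 15,
    pca_dims: int = 10,
    resolution: float = 0.9,
    seed: int = 0,
) -> SegmentationResult:
    """Convenience wrapper: preprocess -> SNN graph -> community detection."""
    emb = preprocess_for_clustering(matrix, pca_dims)
    graph = build_snn_graph(emb, k=k, prune=prune)
    return cluster_pixels(
        graph,
        resolution=resolution,
        seed=seed,
        sample_id=matrix.sample_id,
        parameters={"k": k, "prune": prune, "pca_dims": pca_dims},
    )


def top_cluster_lipids(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    annotations: Optional[Sequence[LipidAnnotation]] = None,
    n: int = 5,
) -> pd.DataFrame:
    """Rank each cluster's defining lipids by median-scaled intensity.

    Every feature is scaled by the global median of its non-zero pixel
    intensities; within each cluster features are ranked by the mean scaled
    intensity and the top ``n`` reported, alongside the mean log2 per-pixel
    intensity.  Features shared between clusters' top lists appear once per
    cluster here; heatmap exports deduplicate.  All-zero features are
    excluded from ranking.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_pixels:
        raise ValueError("labels must cover all matrix pixels")
    if n > matrix.n_features:
        warnings.warn("n exceeds feature count; truncating", stacklevel=2)
        n = matrix.n_features

    names = (
        {i: a for i, a in enumerate(annotations)} if annotations is not None else {}
    )
    values = matrix.values
    scaled = np.zeros_like(values)
    usable = []
    for f in range(matrix.n_features):
        col = values[:, f]
        nzv = col[col > 0]
        if nzv.size == 0:
            continue
        scaled[:, f] = col / np.median(nzv)
        usable.append(f)
    usable = np.asarray(usable, dtype=int)

    rows = []
    for c in np.unique(labels):
        mask = labels == c
        means = scaled[mask][:, usable].mean(axis=0)
        top = usable[np.argsort(-means, kind="stable")][:n]
        for rank, f in enumerate(top, start=1):
            mean_scaled = float(scaled[mask, f].mean())
            with np.errstate(divide="ignore"):
                log2_mean = float(np.log2(values[mask, f].mean())) if values[mask, f].mean() > 0 else float("nan")
            rows.append(
                {
                    "cluster": int(c),
                    "rank": rank,
                    "feature_index": int(f),
                    "feature_mz": float(matrix.feature_mz[f]),
                    "lipid_name": names[f].lipid_name if f in names else "",
                    "mean_scaled_intensity": mean_scaled,
                    "mean_log2_intensity": log2_mean,
                }
            )
    return pd.DataFrame(rows)


def assign_regions(
    result: SegmentationResult, region_map: dict[int, str]
) -> np.ndarray:
    """Propagate the cluster-to-region map to pixels.

    Unmapped clusters become "unassigned" (excluded from group statistics);
    a map naming a non-existent cluster is a configuration error.
    """
    known = set(result.cluster_sizes)
    bad_regions = set(region_map.values()) - REGION_VOCABULARY
    if bad_regions:
        raise ValueError(f"unknown region label(s): {sorted(bad_regions)}")
    bad = set(region_map) - known
    if bad:
        raise ValueError(f"region map names non-existent cluster(s): {sorted(bad)}")
    return np.array(
        [region_map.get(int(c), "unassigned") for c in result.labels], dtype=object
    )


def export_label_raster(
    matrix: FeatureMatrix,
    result: SegmentationResult,
    regions: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Tidy (x, y, cluster, region) raster for TSV/PNG export."""
    df = matrix.pixel_table.copy()
    df["cluster"] = result.labels
    df["region"] = regions if regions is not None else "unassigned"
    return df
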