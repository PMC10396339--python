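"""Cross-species comparative machinery.

Builds the shared 1:1-ortholog gene space, integrates the two species'
datasets into one embedding via CCA anchors (mutual nearest neighbors in
canonically-correlated space, used to estimate per-cell correction
vectors), computes species-normalized cluster composition, and scores
marker-set overlaps with the representation factor and its hypergeometric
p-value.

Unified gene identifiers use the species-B namespace: species-A genes are
renamed to their 1:1 ortholog's B id when the shared space is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .atlas import (
    ClusterAssignment,
    Embedding,
    NormalizedMatrix,
    cluster_louvain,
    knn_graph,
    standardized_variance,
)
from .io_formats import CountMatrix, OrthologTable

__all__ = [
    "SharedGeneSpace",
    "CompositionMatrix",
    "OverlapResult",
    "restrict_to_one2one",
    "integrate_datasets",
    "composition_matrix",
    "representation_factor",
    "hypergeom_pvalue",
    "marker_overlap",
]


@dataclass
class SharedGeneSpace:
    """The 1:1-ortholog gene space retained for cross-species work.

    ``pairs`` lists the retained ortholog pairs; both converted count
    matrices are keyed by the unified (species-B) gene ids, in identical
    order.  ``report`` records how many 1:1 pairs existed and how many
    survived the expressed-in-both filter.
    """

    pairs: pd.DataFrame
    cm_a: CountMatrix
    cm_b: CountMatrix
    report: dict = field(default_factory=dict)

    @property
    def unified_ids(self) -> list[str]:
        return list(self.pairs["gene_B"])

    @property
    def n_genes(self) -> int:
        return len(self.pairs)

    def a_to_unified(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_A"], self.pairs["gene_B"]))


def restrict_to_one2one(
    cm_a: CountMatrix,
    cm_b: CountMatrix,
    orthologs: OrthologTable,
    min_cells: int = 2,
) -> SharedGeneSpace:
    """Restrict both datasets to 1:1 orthologs expressed in both.

    A pair is retained when its gene is resolvable in both matrices and
    has nonzero counts in at least ``min_cells`` cells of each dataset.
    Species-A rows are renamed to the orthologous species-B ids so both
    returned matrices share one gene universe.
    """
    one = orthologs.one2one
    genes_a = set(cm_a.gene_ids)
    genes_b = set(cm_b.gene_ids)
    present = one[
        one["gene_A"].isin(genes_a) & one["gene_B"].isin(genes_b)
    ].reset_index(drop=True)
    if len(present) == 0:
        raise ValueError(
            "no 1:1 ortholog pair is resolvable in both count matrices"
        )

    def expressed_cells(cm: CountMatrix, genes: pd.Series) -> np.ndarray:
        idx = cm.gene_index(genes)
        return np.asarray((cm.counts[idx, :] > 0).sum(axis=1)).ravel()

    ncells_a = expressed_cells(cm_a, present["gene_A"])
    ncells_b = expressed_cells(cm_b, present["gene_B"])
    keep = (ncells_a >= min_cells) & (ncells_b >= min_cells)
    retained = present[keep].reset_index(drop=True)
    if len(retained) == 0:
        raise ValueError(
            "no 1:1 ortholog pair is expressed in both datasets at "
            f"min_cells={min_cells}"
        )
    sub_a = cm_a.subset_genes(list(retained["gene_A"]))
    sub_a.gene_ids = list(retained["gene_B"])  # convert to unified ids
    sub_b = cm_b.subset_genes(list(retained["gene_B"]))
    report = {
        "n_one2one_in_table": int(len(one)),
        "n_resolvable": int(len(present)),
        "n_retained": int(len(retained)),
        "min_cells": int(min_cells),
    }
    return SharedGeneSpace(
        pairs=retained[["gene_A", "gene_B"]], cm_a=sub_a, cm_b=sub_b,
        report=report,
    )


def _standardize_per_gene(x: np.ndarray) -> np.ndarray:
    """Center and unit-scale each column (gene) of a cells x genes array."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return (x - mu) / np.where(sd > 0, sd, 1.0)


def select_anchor_features(
    nm_list: list[NormalizedMatrix], n_features: int
) -> list[str]:
    """Shared highly variable genes, ranked by summed per-dataset rank."""
    ids = nm_list[0].gene_ids
    rank_sum = pd.Series(0.0, index=pd.Index(ids))
    for nm in nm_list:
        sv = standardized_variance(nm)
        rank_sum += sv.rank(ascending=False, method="average")
    ranked = rank_sum.sort_index().sort_values(kind="stable")
    return list(ranked.index[: min(n_features, len(ids))])


def _cca(z1: np.ndarray, z2: np.ndarray, dims: int, seed: int):
    """Top canonical-correlation cell loadings of two standardized sets."""
    from sklearn.utils.extmath import randomized_svd

    m = z1 @ z2.T  # cells1 x cells2 cross-covariance in feature space
    u, s, vt = randomized_svd(m, n_components=dims, random_state=seed)
    cc1 = u / np.linalg.norm(u, axis=1, keepdims=True).clip(min=1e-12)
    cc2 = vt.T / np.linalg.norm(vt.T, axis=1, keepdims=True).clip(min=1e-12)
    return cc1, cc2


def _mutual_nearest_neighbors(
    cc1: np.ndarray, cc2: np.ndarray, k: int
) -> np.ndarray:
    nn12 = NearestNeighbors(n_neighbors=min(k, len(cc2))).fit(cc2)
    _, idx12 = nn12.kneighbors(cc1)
    nn21 = NearestNeighbors(n_neighbors=min(k, len(cc1))).fit(cc1)
    _, idx21 = nn21.kneighbors(cc2)
    set12 = {(i, j) for i in range(len(cc1)) for j in idx12[i]}
    anchors = [
        (int(i), int(j))
        for j in range(len(cc2))
        for i in idx21[j]
        if (int(i), int(j)) in set12
    ]
    return np.array(sorted(anchors), dtype=int).reshape(-1, 2)


def _filter_anchors(
    anchors: np.ndarray, x1: np.ndarray, x2: np.ndarray, k_filter: int = 200
) -> np.ndarray:
    """Drop anchors whose cells are not close in expression space.

    CCA can place genuinely unmatched populations (present in only one
    dataset) near each other; requiring the reference cell to be among
    the query cell's k_filter nearest reference cells in the original
    feature space removes such spurious pairs.
    """
    if len(anchors) == 0 or k_filter >= len(x1):
        return anchors
    nn = NearestNeighbors(n_neighbors=k_filter).fit(x1)
    _, idx = nn.kneighbors(x2[anchors[:, 1]])
    keep = np.array(
        [anchors[a, 0] in idx[a] for a in range(len(anchors))]
    )
    return anchors[keep]


def _score_anchors(
    anchors: np.ndarray, cc1: np.ndarray, cc2: np.ndarray, k_score: int = 30
) -> np.ndarray:
    """Shared-neighbor overlap of each anchor pair in joint CCA space."""
    joint = np.vstack([cc1, cc2])
    k = min(k_score + 1, len(joint))
    nn = NearestNeighbors(n_neighbors=k).fit(joint)
    _, idx = nn.kneighbors(joint)
    neigh = [set(row[1:]) for row in idx]
    n1 = len(cc1)
    raw = np.array(
        [
            len(neigh[i] & neigh[n1 + j]) / max(k - 1, 1)
            for i, j in anchors
        ]
    )
    lo, hi = np.quantile(raw, [0.01, 0.90]) if len(raw) else (0.0, 1.0)
    if hi <= lo:
        return np.ones_like(raw)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


def integrate_datasets(
    nm_list: list[NormalizedMatrix],
    n_anchor_features: int = 3000,
    dims: int = 10,
    k_anchor: int = 5,
    seed: int = 0,
    k_filter: int = 200,
    k_score: int = 30,
    k_weight: int = 100,
    knn_k: int = 20,
    prune: float = 1.0 / 15.0,
    resolution: float = 1.0,
) -> tuple[Embedding, ClusterAssignment, dict]:
    """Anchor-based integration of two datasets sharing one gene universe.

    Steps: (i) anchor features = shared highly variable genes; (ii) CCA
    on the per-dataset standardized feature submatrices; (iii) anchors =
    mutual nearest neighbor cell pairs (k_anchor) in L2-normalized CCA
    space, scored by shared-neighbor overlap; (iv) each query cell is
    corrected by a Gaussian-weighted average of its nearest anchors'
    reference-minus-query difference vectors (bandwidth = distance to the
    k_weight-th anchor); (v) joint PCA, SNN graph (k=20) and Louvain give
    the integrated embedding and clusters.

    The first dataset is the reference.  Returns the joint embedding, the
    integrated cluster assignment, and a diagnostics dict (anchor count,
    features used).
    """
    if len(nm_list) != 2:
        raise ValueError("integration is defined for exactly two datasets")
    nm1, nm2 = nm_list
    if nm1.gene_ids != nm2.gene_ids:
        raise ValueError("datasets must share an identical gene universe")

    features = select_anchor_features(nm_list, n_anchor_features)
    sub1 = nm1.subset_genes(features)
    sub2 = nm2.subset_genes(features)
    x1 = _standardize_per_gene(sub1.dense().T)  # cells x features
    x2 = _standardize_per_gene(sub2.dense().T)

    cca_dims = min(dims * 2, min(len(x1), len(x2)) - 1)
    cc1, cc2 = _cca(x1, x2, cca_dims, seed)
    anchors = _mutual_nearest_neighbors(cc1, cc2, k_anchor)
    anchors = _filter_anchors(anchors, x1, x2, k_filter=k_filter)
    if len(anchors) == 0:
        raise ValueError(
            "no mutual-nearest-neighbor anchors found; increase k_anchor "
            "or the number of anchor features"
        )
    scores = _score_anchors(anchors, cc1, cc2, k_score=k_score)

    # correction vectors for dataset 2 (query) toward dataset 1 (reference)
    diff = x1[anchors[:, 0]] - x2[anchors[:, 1]]  # per-anchor, feature space
    anchor_query_cc = cc2[anchors[:, 1]]
    kw = min(k_weight, len(anchors))
    nn = NearestNeighbors(n_neighbors=kw).fit(anchor_query_cc)
    dist, idx = nn.kneighbors(cc2)
    bandwidth = np.maximum(dist[:, -1], 1e-12)
    gauss = np.exp(-0.5 * (dist / bandwidth[:, None]) ** 2)
    w = gauss * scores[idx]
    w_sum = np.maximum(w.sum(axis=1, keepdims=True), 1e-12)
    n2 = len(x2)
    w_mat = sp.csr_matrix(
        (w.ravel(), (np.repeat(np.arange(n2), kw), idx.ravel())),
        shape=(n2, len(anchors)),
    )
    correction = (w_mat @ diff) / w_sum
    x2_corr = x2 + correction

    joint = np.vstack([x1, x2_corr])
    n_comp = min(dims, min(joint.shape) - 1)
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(joint)
    flip = np.array(
        [np.sign(c[np.argmax(np.abs(c))]) or 1.0 for c in pca.components_]
    )
    coords = coords * flip
    sds = pca.singular_values_ / np.sqrt(max(len(joint) - 1, 1))
    barcodes = list(nm1.barcodes) + list(nm2.barcodes)
    emb = Embedding(coords, sds, barcodes)

    graph = knn_graph(emb, k=knn_k, prune=prune)
    clusters = cluster_louvain(graph, resolution=resolution, seed=seed)
    clusters.barcodes = barcodes
    info = {
        "n_anchors": int(len(anchors)),
        "n_anchor_features": len(features),
        "dims": int(n_comp),
        "dataset_sizes": [nm1.n_cells, nm2.n_cells],
    }
    return emb, clusters, info


@dataclass
class CompositionMatrix:
    """Integrated-cluster by origin counts and normalized fractions.

    Direction ``of_integrated_cluster``: within each integrated cluster,
    origins are weighted by the inverse of their species' total cell
    count, so unequal sample sizes do not masquerade as skew; each row
    sums to 1.  Direction ``of_origin_cluster``: unweighted fraction of
    each origin's cells landing in each integrated cluster; each origin
    column sums to 1.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame
    direction: str

    def __post_init__(self) -> None:
        sums = (
            self.normalized.sum(axis=1)
            if self.direction == "of_integrated_cluster"
            else self.normalized.sum(axis=0)
        )
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise ValueError("normalized fractions do not sum to 1")

    def majority_fraction(self) -> pd.Series:
        """Largest normalized origin fraction per integrated cluster."""
        return self.normalized.max(axis=1)


def composition_matrix(
    integrated: ClusterAssignment | np.ndarray,
    origins: np.ndarray,
    species: np.ndarray,
    direction: str = "of_integrated_cluster",
) -> CompositionMatrix:
    """Cluster composition by origin, normalized for sample-size imbalance.

    ``origins`` can be species labels (species-skew analysis) or
    source-atlas cluster labels (cluster correspondence analysis);
    ``species`` supplies the per-cell species used for 1/N weighting.
    """
    labels = (
        integrated.labels
        if isinstance(integrated, ClusterAssignment)
        else np.asarray(integrated)
    )
    origins = np.asarray(origins)
    species = np.asarray(species)
    if len(origins) != len(labels) or len(species) != len(labels):
        raise ValueError("label vectors must align with the cells")
    if pd.isna(origins).any() or pd.isna(species).any():
        raise ValueError("every cell needs an origin and species label")
    if direction not in ("of_integrated_cluster", "of_origin_cluster"):
        raise ValueError(f"unknown direction: {direction}")

    df = pd.DataFrame(
        {"cluster": labels, "origin": origins, "species": species}
    )
    counts = (
        df.groupby(["cluster", "origin"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    if direction == "of_integrated_cluster":
        species_totals = df["species"].value_counts()
        cell_w = 1.0 / species_totals[df["species"]].to_numpy()
        df["w"] = cell_w
        wsum = (
            df.groupby(["cluster", "origin"], sort=True)["w"]
            .sum()
            .unstack(fill_value=0.0)
        )
        normalized = wsum.div(wsum.sum(axis=1), axis=0)
    else:
        origin_totals = df["origin"].value_counts()
        normalized = counts.div(origin_totals[counts.columns], axis=1)
    return CompositionMatrix(
        counts=counts, normalized=normalized, direction=direction
    )


@dataclass
class OverlapResult:
    """Overlap of two gene sets against a finite universe."""

    k: int
    n1: int
    n2: int
    N: int
    rf: float
    p: float
    shared_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k > min(self.n1, self.n2):
            raise ValueError("overlap exceeds a set size")
        if max(self.n1, self.n2) > self.N:
            raise ValueError("set size exceeds the universe")
        if not (0 <= self.p <= 1 and self.rf >= 0):
            raise ValueError("invalid rf or p")

    def __str__(self) -> str:  # the "p < bound" reporting style
        exponent = np.floor(np.log10(self.p)) if self.p > 0 else -320
        bound = 10.0 ** (exponent + 1)
        return (
            f"overlap k={self.k} (n1={self.n1}, n2={self.n2}, N={self.N}): "
            f"RF={self.rf:.2f}, p-value <{bound:.3g}"
        )


def representation_factor(k: int, n1: int, n2: int, N: int) -> float:
    """Observed overlap over the overlap expected for independent sets.

    rf = k / (n1 * n2 / N).  Values above 1 mean more overlap than
    expected by chance for two sets drawn independently from a universe
    of N genes; below 1, less.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("set sizes must be positive")
    if n1 > N or n2 > N:
        raise ValueError("set sizes cannot exceed the universe")
    if not 0 <= k <= min(n1, n2):
        raise ValueError("k must lie in [0, min(n1, n2)]")
    return k / (n1 * n2 / N)


def hypergeom_pvalue(k: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap of a random n2-subset with a fixed n1-subset of
    an N-gene universe.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("set sizes must be positive")
    if n1 > N or n2 > N:
        raise ValueError("set sizes cannot exceed the universe")
    if not 0 <= k <= min(n1, n2):
        raise ValueError("k must lie in [0, min(n1, n2)]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, n1, n2))


def marker_overlap(
    mt_a,
    clusters_a,
    mt_b,
    clusters_b,
    shared: SharedGeneSpace,
    N_mode: str | int = "shared",
) -> OverlapResult:
    """Representation-factor overlap of pooled marker sets across species.

    Marker genes of the requested clusters are pooled (union) per side,
    restricted to the shared 1:1 gene space, and mapped to unified ids;
    k, n1, n2 are measured after restriction.  The universe N is the
    shared-space size (``N_mode='shared'``, the cross-species default) or
    a configured annotation total for within-species comparisons.
    """
    a_map = shared.a_to_unified()
    unified = set(shared.unified_ids)

    raw_a = mt_a.genes_for(clusters_a)
    # species-A marker tables may already be in unified ids (when markers
    # were computed on the converted matrix) or in native A ids
    set_a = {a_map.get(g, g) for g in raw_a} & unified
    set_b = mt_b.genes_for(clusters_b) & unified

    if isinstance(N_mode, str):
        if N_mode != "shared":
            raise ValueError("N_mode must be 'shared' or an integer")
        N = shared.n_genes
    else:
        N = int(N_mode)
    n1, n2 = len(set_a), len(set_b)
    shared_genes = sorted(set_a & set_b)
    k = len(shared_genes)
    if n1 == 0 or n2 == 0:
        warnings.warn(
            "a marker set is empty after restriction to the shared space",
            stacklevel=2,
        )
        return OverlapResult(
            k=0, n1=n1, n2=n2, N=N, rf=0.0, p=1.0, shared_genes=[]
        )
    rf = representation_factor(k, n1, n2, N)
    p = hypergeom_pvalue(k, n1, n2, N)
    return OverlapResult(
        k=k, n1=n1, n2=n2, N=N, rf=rf, p=p, shared_genes=shared_genes
    )
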