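"""Single-species atlas construction.

The stage chain is: depth normalization with optional covariate
regression, highly-variable-gene selection, PCA with an elbow rule for
the number of informative components, a shared-nearest-neighbor (SNN)
graph with k=20, Louvain community detection, and a UMAP embedding for
visualisation.  Every stage is a pure function of its inputs and the
seeds in the parameters, so an atlas is exactly reproducible.

Normalization is log1p of depth-scaled counts followed by per-gene
ordinary-least-squares regression of nuisance covariates (rRNA content,
mitochondrial fraction); the residuals keep each gene's mean.  This is a
deliberately simple variance-stabilising transform with covariate
removal — it is not a regularized negative-binomial model, and the
provenance field records exactly what was applied.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_formats import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "Embedding",
    "ClusterAssignment",
    "AtlasParams",
    "AtlasResult",
    "normalize",
    "select_hvg",
    "embed_pca",
    "choose_pcs",
    "knn_graph",
    "cluster_louvain",
    "umap_embed",
    "run_atlas",
]


@dataclass
class NormalizedMatrix:
    """Genes x cells normalized expression linked to its source ids."""

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    barcodes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("values shape does not match id lists")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_genes(self, gene_ids: list[str]) -> "NormalizedMatrix":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([lookup[g] for g in gene_ids], dtype=int)
        vals = self.values[idx, :] if sp.issparse(self.values) else self.values[idx]
        return NormalizedMatrix(
            vals, list(gene_ids), list(self.barcodes), dict(self.provenance)
        )


@dataclass
class Embedding:
    """Cells x d coordinates with per-component standard deviations."""

    coords: np.ndarray
    sds: np.ndarray
    barcodes: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.sds) > 1e-9):
            raise ValueError("component sds must be non-increasing")


@dataclass
class ClusterAssignment:
    """Integer cluster label per cell, 0-based, ordered by cluster size."""

    labels: np.ndarray
    resolution: float
    seed: int
    barcodes: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cells_in(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def normalize(
    cm: CountMatrix,
    covariates: np.ndarray | pd.DataFrame | None = None,
    scale_factor: float = 1e4,
) -> NormalizedMatrix:
    """Depth-normalize, log-transform, and regress out covariates.

    value = log1p(count / cell_total * scale_factor); cells with zero
    total counts get all-zero values (with a warning).  If covariates are
    given (one column per nuisance variable, one row per cell), each
    gene's values are replaced by the OLS residual of value ~ covariates
    plus the gene's mean, which removes linear covariate trends while
    preserving expression level.
    """
    counts = cm.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero_cells = totals == 0
    if zero_cells.any():
        warnings.warn(
            f"{int(zero_cells.sum())} cells have zero total counts; "
            "their normalized values are 0",
            stacklevel=2,
        )
    scale = np.where(zero_cells, 0.0, scale_factor / np.maximum(totals, 1e-12))
    scaled = counts @ sp.diags(scale)
    scaled.data = np.log1p(scaled.data)
    provenance = {
        "scale_factor": scale_factor,
        "transform": "log1p(count/total*scale_factor)",
        "regressed_covariates": [],
    }
    if covariates is None:
        return NormalizedMatrix(
            scaled.tocsc(), list(cm.gene_ids), list(cm.barcodes), provenance
        )

    if isinstance(covariates, pd.DataFrame):
        cov_names = list(covariates.columns)
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == 1 and cm.n_cells != 1:
            cov = cov.T
        cov_names = [f"cov{i}" for i in range(cov.shape[1])]
    if cov.shape[0] != cm.n_cells:
        raise ValueError("covariate rows must match the number of cells")

    y = np.asarray(scaled.todense())  # genes x cells
    design = np.column_stack([np.ones(cm.n_cells), cov])
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    residual = y - (design @ beta).T
    values = residual + y.mean(axis=1, keepdims=True)
    provenance["regressed_covariates"] = cov_names
    return NormalizedMatrix(
        values, list(cm.gene_ids), list(cm.barcodes), provenance
    )


def standardized_variance(nm: NormalizedMatrix) -> pd.Series:
    """Variance of clipped z-scores under a mean-variance trend fit.

    The expected variance of each gene is predicted from the *rank* of
    its mean by a quadratic fit of log10(variance) over genes with
    positive variance — using mean ranks keeps the fit invariant under
    monotone (e.g. constant-shift) transforms of the values; z-scores
    against that expectation are clipped at sqrt(n_cells) before their
    variance is taken, so single outlier cells cannot dominate.
    """
    from scipy.stats import rankdata

    x = nm.dense()
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if nm.n_cells > 1 else np.zeros(nm.n_genes)
    informative = var > 0
    out = pd.Series(0.0, index=pd.Index(nm.gene_ids, name="gene_id"))
    if informative.sum() < 3:
        return out
    q = rankdata(mean) / len(mean)
    lv = np.log10(var[informative])
    coef = np.polyfit(q[informative], lv, deg=min(2, informative.sum() - 1))
    expected_sd = np.sqrt(10.0 ** np.polyval(coef, q))
    clip = np.sqrt(nm.n_cells)
    z = (x - mean[:, None]) / expected_sd[:, None]
    np.clip(z, -clip, clip, out=z)
    std_var = z.var(axis=1, ddof=1)
    std_var[~informative] = 0.0
    out[:] = std_var
    return out


def select_hvg(nm: NormalizedMatrix, n_top: int) -> list[str]:
    """Top highly variable genes by standardized variance.

    Deterministic: ties (and the no-signal case of a constant matrix)
    fall back to lexicographic gene-id order.
    """
    if n_top < 1:
        raise ValueError("n_top must be at least 1")
    if n_top > nm.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds {nm.n_genes} genes; returning all",
            stacklevel=2,
        )
        n_top = nm.n_genes
    sv = standardized_variance(nm)
    if (sv == 0).all():
        warnings.warn(
            "no informative genes (constant matrix?); returning "
            "lexicographic order",
            stacklevel=2,
        )
    ranked = sv.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n_top])


def embed_pca(
    nm: NormalizedMatrix,
    genes: list[str] | None = None,
    n_components: int = 50,
) -> Embedding:
    """Centered, unit-scaled PCA of cells over the given genes.

    Deterministic up to sign; signs are fixed by making the
    largest-magnitude entry of each loading vector positive.
    """
    if nm.n_cells < 2:
        raise ValueError("PCA needs at least 2 cells")
    sub = nm.subset_genes(genes) if genes is not None else nm
    x = sub.dense().T  # cells x genes
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    x = x / np.where(sd > 0, sd, 1.0)
    max_rank = min(x.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; "
            "truncating",
            stacklevel=2,
        )
        n_components = max_rank
    pca = PCA(
        n_components=n_components, svd_solver="randomized", random_state=0
    )
    coords = pca.fit_transform(x)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.array(
        [
            np.sign(comp[np.argmax(np.abs(comp))]) or 1.0
            for comp in pca.components_
        ]
    )
    coords = coords * flip
    sds = pca.singular_values_ / np.sqrt(max(x.shape[0] - 1, 1))
    order = np.argsort(-sds, kind="stable")
    return Embedding(coords[:, order], sds[order], list(sub.barcodes))


def choose_pcs(
    sds: np.ndarray,
    frac_threshold: float = 0.05,
    drop_threshold: float = 0.001,
    override: int | None = None,
) -> int:
    """Number of principal components to keep, by a two-part elbow rule.

    Returns the smallest i such that component i contributes less than
    ``frac_threshold`` of the total standard deviation AND every
    consecutive drop from component i onward is below ``drop_threshold``
    of the total (i.e. i sits past the last appreciable drop in the
    spectrum).  Components past the elbow must sit strictly below the
    first component, so a flat spectrum has no elbow and the full length
    is returned.  ``override`` short-circuits the rule, for datasets
    where the number of informative components was fixed by inspection.
    """
    sds = np.asarray(sds, dtype=float)
    if override is not None:
        return int(override)
    if len(sds) < 2:
        return len(sds)
    total = sds.sum()
    if total == 0:
        return len(sds)
    frac = sds / total
    drops = frac[:-1] - frac[1:]
    for i in range(1, len(sds)):
        if (
            frac[i] < frac_threshold
            and np.all(drops[i - 1:] < drop_threshold)
            and sds[i] < sds[0]
        ):
            return i
    return len(sds)


def knn_graph(
    emb: Embedding,
    k: int = 20,
    n_pcs: int | None = None,
    prune: float = 1.0 / 15.0,
) -> igraph.Graph:
    """SNN-weighted k-nearest-neighbor graph of cells.

    Edges connect each cell to its k Euclidean nearest neighbors (ties
    broken by cell index); each edge is weighted by the Jaccard overlap
    of the two cells' neighbor sets (self included) and dropped when the
    weight falls below ``prune``.
    """
    coords = emb.coords if n_pcs is None else emb.coords[:, :n_pcs]
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self in column 0 (usually)
    # guarantee self-inclusion regardless of duplicate-coordinate ties
    rows = np.repeat(np.arange(n), k + 1)
    cols = idx.ravel()
    member = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    member = ((member + sp.eye(n, format="csr")) > 0).astype(np.int32)

    knn_edges = member.copy()
    knn_edges.setdiag(0)
    knn_edges.eliminate_zeros()
    mask = ((knn_edges + knn_edges.T) > 0).astype(np.int32)

    inter = (member @ member.T).multiply(mask)
    inter = sp.coo_matrix(sp.triu(inter, k=1))
    set_sizes = np.asarray(member.sum(axis=1)).ravel()
    union = set_sizes[inter.row] + set_sizes[inter.col] - inter.data
    jacc = inter.data / union
    keep = jacc >= prune
    edges = list(zip(inter.row[keep].tolist(), inter.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges, directed=False)
    g.es["weight"] = jacc[keep].tolist()
    return g


def cluster_louvain(
    graph: igraph.Graph, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Louvain community detection, labels ordered by decreasing size."""
    if graph.vcount() == 0:
        raise ValueError("cannot cluster an empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    state = random.getstate()
    try:
        random.seed(seed)
        part = graph.community_multilevel(
            weights="weight" if "weight" in graph.es.attributes() else None,
            resolution=resolution,
        )
    finally:
        random.setstate(state)
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts()
    # decreasing size, ties by original label for stability
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])
    return ClusterAssignment(labels=labels, resolution=resolution, seed=seed)


def umap_embed(emb: Embedding, seed: int = 0, n_pcs: int | None = None) -> np.ndarray:
    """2-D UMAP of an embedding, deterministic at a fixed seed."""
    import umap  # deferred: numba compilation is slow to import

    coords = emb.coords if n_pcs is None else emb.coords[:, :n_pcs]
    n = coords.shape[0]
    if n < 3:
        raise ValueError("UMAP needs at least 3 cells")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(15, n - 1),
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        return reducer.fit_transform(coords)


@dataclass
class AtlasParams:
    """Tunable knobs of the atlas stage chain."""

    scale_factor: float = 1e4
    n_hvg: int = 2000
    n_pcs: int | str = "auto"  # int override or "auto" elbow rule
    max_pcs: int = 50
    knn_k: int = 20
    prune: float = 1.0 / 15.0
    resolution: float = 1.0
    seed: int = 0
    run_umap: bool = False


@dataclass
class AtlasResult:
    normalized: NormalizedMatrix
    hvg: list[str]
    embedding: Embedding
    n_pcs_used: int
    graph: igraph.Graph
    clusters: ClusterAssignment
    umap: np.ndarray | None = None


def run_atlas(
    cm: CountMatrix,
    params: AtlasParams | None = None,
    covariates: pd.DataFrame | None = None,
) -> AtlasResult:
    """Run the full single-species atlas chain on one count matrix."""
    p = params or AtlasParams()
    nm = normalize(cm, covariates=covariates, scale_factor=p.scale_factor)
    hvg = select_hvg(nm, p.n_hvg)
    emb = embed_pca(nm, genes=hvg, n_components=p.max_pcs)
    n_pcs = (
        choose_pcs(emb.sds)
        if p.n_pcs == "auto"
        else choose_pcs(emb.sds, override=int(p.n_pcs))
    )
    graph = knn_graph(emb, k=p.knn_k, n_pcs=n_pcs, prune=p.prune)
    clusters = cluster_louvain(graph, resolution=p.resolution, seed=p.seed)
    clusters.barcodes = list(cm.barcodes)
    coords2d = umap_embed(emb, seed=p.seed, n_pcs=n_pcs) if p.run_umap else None
    return AtlasResult(
        normalized=nm,
        hvg=hvg,
        embedding=emb,
        n_pcs_used=n_pcs,
        graph=graph,
        clusters=clusters,
        umap=coords2d,
    )
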