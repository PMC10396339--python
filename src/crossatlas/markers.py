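"""Cluster marker-gene detection by Wilcoxon rank-sum test.

A gene is a marker of a cluster when it is expressed in at least 5% of
the cluster's cells, its natural-log fold change of average expression
versus all other cells is at least 0.25, and its Bonferroni-adjusted
rank-sum p-value clears the significance level.  Fold changes are
computed on de-logged normalized values with a pseudocount of 1
(the Seurat convention), so the 0.25 threshold is on the natural-log
scale.  Only up-regulated markers are reported by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ClusterAssignment, NormalizedMatrix

__all__ = ["MarkerTable", "wilcoxon_rank_sum", "find_markers"]

MARKER_COLUMNS = [
    "cluster_id", "gene_id", "log_fc", "pct_in", "pct_out", "p_raw", "p_adj",
]


@dataclass
class MarkerTable:
    """Admitted marker rows: one per (cluster, gene) passing thresholds."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MARKER_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        self.table = self.table[MARKER_COLUMNS].reset_index(drop=True)

    def genes_for(self, clusters: int | list[int]) -> set[str]:
        """Pooled (union) marker genes of one or several clusters."""
        if np.isscalar(clusters):
            clusters = [clusters]
        mask = self.table["cluster_id"].isin(list(clusters))
        return set(self.table.loc[mask, "gene_id"])

    def __len__(self) -> int:
        return len(self.table)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of x, two-sided p).  The null distribution is
    enumerated exactly for combined samples of at most 12 values without
    ties; otherwise the normal approximation with tie and continuity
    corrections is used.  Degenerate case: when every value in both
    groups is identical the test is uninformative and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(pooled) <= 12
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _expm1_means_and_pcts(
    dense: np.ndarray, in_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ex = np.expm1(dense)
    mean_in = ex[:, in_mask].mean(axis=1)
    mean_out = ex[:, ~in_mask].mean(axis=1)
    pct_in = (dense[:, in_mask] > 0).mean(axis=1)
    pct_out = (dense[:, ~in_mask] > 0).mean(axis=1)
    return mean_in, mean_out, pct_in, pct_out


def find_markers(
    nm: NormalizedMatrix,
    clusters: ClusterAssignment,
    min_pct: float = 0.05,
    min_logfc: float = 0.25,
    alpha: float = 0.05,
    min_pct_both: bool = False,
) -> MarkerTable:
    """Positive marker genes per cluster versus all other cells.

    For each cluster, genes passing the expression-fraction and natural-
    log fold-change admission thresholds are rank-sum tested in-cluster
    versus all remaining cells; p-values are Bonferroni-corrected by the
    total number of genes in the matrix and rows with adjusted p <= alpha
    are returned.

    log_fc = ln((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1)).
    ``min_pct_both`` additionally requires the out-group to reach the
    expression fraction (off by default: the criterion reads on the
    cluster's own cells).
    """
    labels = np.asarray(clusters.labels)
    if len(labels) != nm.n_cells:
        raise ValueError("cluster assignment does not cover the matrix cells")
    n_clusters = int(labels.max()) + 1 if len(labels) else 0
    if n_clusters < 2:
        warnings.warn(
            "fewer than two clusters: no reference group, marker table empty",
            stacklevel=2,
        )
        return MarkerTable(pd.DataFrame(columns=MARKER_COLUMNS))

    dense = nm.dense()
    n_genes_total = nm.n_genes
    gene_ids = np.asarray(nm.gene_ids)
    rows = []
    for c in range(n_clusters):
        in_mask = labels == c
        mean_in, mean_out, pct_in, pct_out = _expm1_means_and_pcts(
            dense, in_mask
        )
        log_fc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        admitted = pct_in >= min_pct
        if min_pct_both:
            admitted &= pct_out >= min_pct
        admitted &= log_fc >= min_logfc
        idx = np.flatnonzero(admitted)
        if len(idx) == 0:
            continue
        x = dense[np.ix_(idx, in_mask)]
        y = dense[np.ix_(idx, ~in_mask)]
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=RuntimeWarning)
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=1,
            )
        p_raw = np.asarray(res.pvalue, dtype=float)
        # zero-variance rows (all values tied) are uninformative
        tied = np.array(
            [np.all(np.concatenate([xi, yi]) == xi[0])
             for xi, yi in zip(x, y)]
        )
        p_raw[tied] = 1.0
        p_adj = np.minimum(1.0, p_raw * n_genes_total)
        keep = p_adj <= alpha
        for j in np.flatnonzero(keep):
            gi = idx[j]
            rows.append(
                (
                    c, gene_ids[gi], float(log_fc[gi]),
                    float(pct_in[gi]), float(pct_out[gi]),
                    float(p_raw[j]), float(p_adj[j]),
                )
            )
    return MarkerTable(pd.DataFrame(rows, columns=MARKER_COLUMNS))
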