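"""Per-cell quality control.

Cells are summarised by genes detected, total transcripts, and the
fraction of transcripts from mitochondrial genes, then filtered against
per-sample thresholds.  Boundary semantics follow the "more than 5%"
style rule: a cell is removed only when a metric is *strictly* outside
its allowed range, so cells sitting exactly on a threshold are retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = ["QCThresholds", "compute_cell_qc", "filter_cells"]


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive per-cell QC bounds; defaults keep everything."""

    min_genes: int = 0
    max_genes: float = math.inf
    min_counts: int = 0
    max_counts: float = math.inf
    max_mito_frac: float = 1.0
    mito_gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes exceeds max_genes")
        if self.min_counts > self.max_counts:
            raise ValueError("min_counts exceeds max_counts")
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must lie in [0, 1]")


def compute_cell_qc(
    cm: CountMatrix, mito_gene_ids: Iterable[str] = ()
) -> pd.DataFrame:
    """Per-cell QC metrics: genes detected, total counts, mito fraction.

    ``mito_frac`` is mitochondrial counts over total counts, defined as 0
    for cells with zero total counts or when no mito genes are given.
    """
    mito = set(mito_gene_ids)
    unknown = mito - set(cm.gene_ids)
    if unknown:
        raise ValueError(
            f"mito gene ids not present in matrix: {sorted(unknown)[:5]}"
        )
    counts = cm.counts.tocsc()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    n_counts = np.asarray(counts.sum(axis=0)).ravel()
    if mito:
        idx = cm.gene_index(sorted(mito))
        mito_counts = np.asarray(counts[idx, :].sum(axis=0)).ravel()
    else:
        mito_counts = np.zeros_like(n_counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(n_counts > 0, mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": cm.barcodes,
            "n_genes": n_genes.astype(int),
            "n_counts": n_counts.astype(int),
            "mito_frac": mito_frac,
        }
    )


def filter_cells(
    cm: CountMatrix, thresholds: QCThresholds
) -> tuple[CountMatrix, dict]:
    """Filter cells by QC thresholds; returns (filtered matrix, report).

    A removed cell is attributed to *every* rule it violates, so the
    per-rule counts in the report can exceed the number removed.
    """
    qc = compute_cell_qc(cm, thresholds.mito_gene_ids)
    viol = {
        "min_genes": qc["n_genes"] < thresholds.min_genes,
        "max_genes": qc["n_genes"] > thresholds.max_genes,
        "min_counts": qc["n_counts"] < thresholds.min_counts,
        "max_counts": qc["n_counts"] > thresholds.max_counts,
        "max_mito_frac": qc["mito_frac"] > thresholds.max_mito_frac,
    }
    removed = np.zeros(cm.n_cells, dtype=bool)
    for mask in viol.values():
        removed |= mask.to_numpy()
    keep = ~removed
    if not keep.any():
        warnings.warn("QC thresholds removed every cell", stacklevel=2)
    report = {
        "n_in": int(cm.n_cells),
        "n_out": int(keep.sum()),
        "n_removed": int(removed.sum()),
        "n_removed_by_rule": {k: int(v.sum()) for k, v in viol.items()},
    }
    return cm.subset_cells(keep), report
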