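"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices travel as CellRanger-style Matrix Market triplets
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, gzipped or plain,
genes as rows).  Ortholog relationships travel as a three-column TSV.
A small GTF utility collapses each transcript's exons into a single
spanning exon so that unspliced (nuclear) reads align to a "pre-mRNA"
reference.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "OrthologTable",
    "FormatError",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_ortholog_table",
    "write_ortholog_table",
    "gtf_to_premrna",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


@dataclass
class CountMatrix:
    """Sparse genes x cells integer count matrix with identifiers.

    Parameters
    ----------
    counts
        ``scipy.sparse`` matrix, genes as rows, cells as columns,
        non-negative integers.
    gene_ids
        Unique gene identifiers, one per row.
    barcodes
        Unique cell barcodes, one per column.
    sample_id, species
        Free-text labels recorded in provenance.
    cell_meta
        Optional per-cell metadata (timepoint, cell-type truth, ...);
        indexed like ``barcodes``.
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    barcodes: list[str]
    sample_id: str = ""
    species: str = ""
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        if len(set(self.barcodes)) != n_cells:
            raise FormatError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise FormatError("non-integer counts")
        self.counts.data = np.round(self.counts.data)
        if self.cell_meta is not None and len(self.cell_meta) != n_cells:
            raise FormatError("cell_meta length does not match barcodes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Row indices of the given gene ids (raises on unknown id)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        idx = self.gene_index(gene_ids)
        return CountMatrix(
            self.counts[idx, :],
            list(gene_ids),
            list(self.barcodes),
            sample_id=self.sample_id,
            species=self.species,
            cell_meta=None if self.cell_meta is None else self.cell_meta.copy(),
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            self.counts[:, idx],
            list(self.gene_ids),
            [self.barcodes[i] for i in idx],
            sample_id=self.sample_id,
            species=self.species,
            cell_meta=(
                None
                if self.cell_meta is None
                else self.cell_meta.iloc[idx].reset_index(drop=True)
            ),
        )


RELATIONS = ("one2one", "one2many", "many2many")


@dataclass
class OrthologTable:
    """Cross-species gene pairs with a relation class.

    The ``one2one`` subset must be a bijection: each gene appears at most
    once on its side of the table.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = ["gene_A", "gene_B", "relation"]
        if list(self.table.columns[:3]) != required:
            self.table = self.table.copy()
            self.table.columns = required + list(self.table.columns[3:])
        bad = set(self.table["relation"]) - set(RELATIONS)
        if bad:
            raise FormatError(f"unknown relation classes: {sorted(bad)}")
        one = self.one2one
        for col in ("gene_A", "gene_B"):
            dup = one[col][one[col].duplicated()]
            if len(dup):
                raise FormatError(
                    f"one2one gene repeated on side {col}: {sorted(set(dup))[:5]}"
                )

    @property
    def one2one(self) -> pd.DataFrame:
        return self.table[self.table["relation"] == "one2one"]

    def a_to_b(self) -> dict[str, str]:
        """The 1:1 mapping from species-A ids to species-B ids."""
        one = self.one2one
        return dict(zip(one["gene_A"], one["gene_B"]))

    def __len__(self) -> int:
        return len(self.table)


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_triplet_file(dir_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dir_path / (stem + suffix)
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {dir_path}")


def _read_id_column(path: Path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx_triplet(
    dir_path: str | os.PathLike,
    sample_id: str = "",
    species: str = "",
) -> CountMatrix:
    """Read a CellRanger-style MTX triplet directory into a CountMatrix.

    Expects ``matrix.mtx[.gz]``, ``features.tsv[.gz]`` (or ``genes.tsv``)
    and ``barcodes.tsv[.gz]``.  Gene order follows the features file;
    duplicated coordinate entries are summed per the Matrix Market
    coordinate convention.  An optional ``cell_meta.tsv[.gz]`` is read
    into per-cell metadata.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_triplet_file(dir_path, ("matrix.mtx",))
    feat_path = _find_triplet_file(dir_path, ("features.tsv", "genes.tsv"))
    bc_path = _find_triplet_file(dir_path, ("barcodes.tsv",))

    try:
        with _open_maybe_gzip(mtx_path, "rt") as fh:
            mat = scipy.io.mmread(io.StringIO(fh.read()))
    except Exception as exc:  # scipy raises bare ValueError on bad files
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx_path} contains non-integer values")
    mat = sp.csc_matrix(mat)  # sums duplicate coordinates

    gene_ids = _read_id_column(feat_path)
    barcodes = _read_id_column(bc_path)
    if mat.shape[0] != len(gene_ids):
        raise FormatError(
            f"matrix has {mat.shape[0]} rows but features file lists "
            f"{len(gene_ids)} genes"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[1]} columns but barcodes file lists "
            f"{len(barcodes)} cells"
        )

    cell_meta = None
    try:
        meta_path = _find_triplet_file(dir_path, ("cell_meta.tsv",))
    except FormatError:
        meta_path = None
    if meta_path is not None:
        cell_meta = pd.read_csv(meta_path, sep="\t")

    return CountMatrix(
        mat, gene_ids, barcodes, sample_id=sample_id, species=species,
        cell_meta=cell_meta,
    )


def write_mtx_triplet(
    cm: CountMatrix, dir_path: str | os.PathLike, gzipped: bool = False
) -> None:
    """Write a CountMatrix as an MTX triplet directory (1-based coords)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    coo = sp.coo_matrix(cm.counts)
    order = np.lexsort((coo.row, coo.col))  # column-major, CellRanger style
    with _open_maybe_gzip(dir_path / ("matrix.mtx" + suffix), "wt") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{cm.n_genes} {cm.n_cells} {coo.nnz}\n")
        for i in order:
            fh.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {int(coo.data[i])}\n")

    with _open_maybe_gzip(dir_path / ("features.tsv" + suffix), "wt") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with _open_maybe_gzip(dir_path / ("barcodes.tsv" + suffix), "wt") as fh:
        for b in cm.barcodes:
            fh.write(b + "\n")
    if cm.cell_meta is not None:
        cm.cell_meta.to_csv(
            dir_path / ("cell_meta.tsv" + suffix), sep="\t", index=False
        )


def read_ortholog_table(path: str | os.PathLike) -> OrthologTable:
    """Read a TSV of ortholog pairs into a validated OrthologTable.

    The file needs columns geneA / geneB and optionally a relation class.
    When the relation column is absent it is inferred from multiplicity:
    a pair is one2one only if both genes occur exactly once in the whole
    table; one2many if exactly one side is repeated; many2many otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("ortholog table needs at least two columns")
    df = df.rename(
        columns={df.columns[0]: "gene_A", df.columns[1]: "gene_B"}
    )
    if df.shape[1] >= 3:
        df = df.rename(columns={df.columns[2]: "relation"})
    else:
        df["relation"] = infer_relations(df["gene_A"], df["gene_B"])
    return OrthologTable(df[["gene_A", "gene_B", "relation"]])


def infer_relations(gene_a: pd.Series, gene_b: pd.Series) -> pd.Series:
    """Classify each pair from gene multiplicities within the table."""
    count_a = gene_a.map(gene_a.value_counts())
    count_b = gene_b.map(gene_b.value_counts())
    relation = pd.Series("one2one", index=gene_a.index)
    relation[(count_a > 1) ^ (count_b > 1)] = "one2many"
    relation[(count_a > 1) & (count_b > 1)] = "many2many"
    return relation


def write_ortholog_table(ot: OrthologTable, path: str | os.PathLike) -> None:
    ot.table.to_csv(path, sep="\t", index=False)


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part[len(key):].strip(" =").strip('"')
    return None


def gtf_to_premrna(
    gtf_in: str | os.PathLike,
    gtf_out: str | os.PathLike,
    collapse: str = "transcript",
) -> dict[str, int]:
    """Collapse exon annotations so unspliced reads count toward genes.

    Every transcript's exon set is replaced by a single exon spanning
    min(start)..max(end) of that transcript (1-based inclusive GTF
    coordinates; strand and attributes of the first exon are preserved).
    Non-exon lines pass through unchanged.  ``collapse='gene'`` collapses
    per gene instead (one spanning exon per gene_id).

    Returns a summary ``{n_transcripts, n_exons_in, n_exons_out}``.
    """
    if collapse not in ("transcript", "gene"):
        raise ValueError("collapse must be 'transcript' or 'gene'")
    key_attr = "transcript_id" if collapse == "transcript" else "gene_id"

    # First pass: per-group spans, and which exon line is each group's first.
    spans: dict[str, list] = {}
    with _open_maybe_gzip(Path(gtf_in)) as fh:
        lines = fh.readlines()

    n_exons_in = 0
    order: list[str] = []
    for lineno, line in enumerate(lines):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9 or fields[2] != "exon":
            continue
        n_exons_in += 1
        key = _gtf_attribute(fields[8], key_attr)
        if key is None:
            raise FormatError(
                f"exon line {lineno + 1} lacks a {key_attr} attribute"
            )
        start, end = int(fields[3]), int(fields[4])
        if key not in spans:
            spans[key] = [start, end, lineno]
            order.append(key)
        else:
            spans[key][0] = min(spans[key][0], start)
            spans[key][1] = max(spans[key][1], end)

    first_lineno = {v[2]: k for k, v in spans.items()}
    with _open_maybe_gzip(Path(gtf_out), "wt") as out:
        for lineno, line in enumerate(lines):
            if line.startswith("#") or not line.strip():
                out.write(line)
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                out.write(line)
                continue
            key = first_lineno.get(lineno)
            if key is None:
                continue  # later exon of an already-emitted group
            start, end, _ = spans[key]
            fields[3], fields[4] = str(start), str(end)
            out.write("\t".join(fields) + "\n")

    n_transcripts = len(spans)
    return {
        "n_transcripts": n_transcripts,
        "n_exons_in": n_exons_in,
        "n_exons_out": n_transcripts,
    }
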