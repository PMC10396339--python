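"""Synthetic paired two-species single-cell datasets with known ground truth.

The generator emulates the structure of a comparative snRNA-seq study of
two related species: each species' transcriptome shares a block of 1:1
orthologous genes (plus some 1:many pairs and species-private genes), and
cells belong to discrete types driven by gene *programs* — sets of genes
up-regulated by a common fold change.  Shared types exist in both species
with programs mapped through the 1:1 ortholog bijection and partially
rewired ("divergence"); species-specific types exist in only one species.
Counts are negative-binomial (gamma-Poisson) with log-normal library-size
variation, mild per-timepoint global shifts, and designated mitochondrial
and rRNA covariate genes.

A separate helper produces the bulk "whole embryo / dissociated cells /
isolated nuclei" triplet used by the concordance module: two vectors are
the embryo expectation perturbed per-gene by a log2-normal isolation bias
of known standard deviation, then Poisson-sampled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, OrthologTable

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "BulkTriplet",
    "generate_paired_datasets",
    "generate_bulk_triplet",
]


class ConfigurationError(ValueError):
    """A SynthConfig violates one of its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth design of a paired two-species simulation.

    Defaults give eight shared cell types plus one species-specific type
    per species, 100 cells per type per timepoint over three timepoints,
    3000 genes per species of which 2000 are 1:1 orthologs.
    """

    n_types_shared: int = 8
    n_types_specific_A: int = 1
    n_types_specific_B: int = 1
    cells_per_type_per_timepoint: int = 100
    n_timepoints: int = 3
    genes_per_species: int = 3000
    n_one2one: int = 2000
    n_one2many: int = 100
    program_size: int = 30
    program_effect: float = 10.0
    divergence_frac: float = 0.2
    nb_dispersion: float = 0.5
    libsize_lognormal_sigma: float = 0.3
    mito_frac_mean: float = 0.02
    rrna_frac_mean: float = 0.05
    seed: int = 1
    # Fraction of each species-specific program placed on 1:1 ortholog
    # genes (genes present in both species but deployed in only one,
    # piwil3-style); the remainder uses species-private genes.  Programs
    # on private genes are invisible to ortholog-restricted integration,
    # so a specific type is only detectable as a skewed integrated
    # cluster through its ortholog-resident program genes.
    specific_ortholog_frac: float = 1.0
    n_mito_genes: int = 10
    n_rrna_genes: int = 10
    baseline_log_mean: float = float(np.log(0.25))
    baseline_log_sigma: float = 1.0
    timepoint_shift_sigma: float = 0.05

    def validate(self) -> None:
        if self.n_one2one + self.n_one2many > self.genes_per_species:
            raise ConfigurationError(
                "n_one2one + n_one2many exceeds genes_per_species"
            )
        if self.n_one2one + 2 * self.n_one2many > self.genes_per_species:
            raise ConfigurationError(
                "one2many pairs need two target genes each: "
                "n_one2one + 2*n_one2many exceeds genes_per_species"
            )
        for name in (
            "n_types_shared", "cells_per_type_per_timepoint", "n_timepoints",
            "genes_per_species", "n_one2one", "program_size",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("n_types_specific_A", "n_types_specific_B", "n_one2many"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not self.program_effect > 1:
            raise ConfigurationError("program_effect must exceed 1")
        if not 0 <= self.divergence_frac <= 1:
            raise ConfigurationError("divergence_frac must lie in [0, 1]")
        if not self.nb_dispersion > 0:
            raise ConfigurationError("nb_dispersion must be strictly positive")
        if self.libsize_lognormal_sigma < 0:
            raise ConfigurationError("libsize_lognormal_sigma must be >= 0")
        for name in ("mito_frac_mean", "rrna_frac_mean"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if not 0 <= self.specific_ortholog_frac <= 1:
            raise ConfigurationError(
                "specific_ortholog_frac must lie in [0, 1]"
            )
        # every program must fit in disjoint gene pools
        n_types = (
            self.n_types_shared
            + self.n_types_specific_A
            + self.n_types_specific_B
        )
        if n_types * self.program_size > self.n_one2one:
            raise ConfigurationError(
                "programs cannot be disjoint: too many program genes for "
                "the 1:1 ortholog pool"
            )

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset pair.

    ``programs[(species, type_name)]`` lists the gene ids (in that
    species' namespace) whose mean is multiplied by the program effect in
    cells of that type.  ``specificity[type_name]`` is one of ``shared``,
    ``A_only``, ``B_only``.  Per-cell labels (cell type, timepoint,
    species) live in each CountMatrix's ``cell_meta``.
    """

    programs: dict[tuple[str, str], list[str]]
    specificity: dict[str, str]
    mito_genes: dict[str, list[str]]
    rrna_genes: dict[str, list[str]]
    config: SynthConfig
    cell_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def program_genes(self, species: str, type_name: str) -> list[str]:
        return self.programs[(species, type_name)]


def _gene_ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _species_counts(
    cfg: SynthConfig,
    rng: np.random.Generator,
    baselines: np.ndarray,
    type_names: list[str],
    programs: dict[str, np.ndarray],
) -> tuple[sp.csc_matrix, pd.DataFrame]:
    """NB counts for one species, cells grouped by (type, timepoint)."""
    n_genes = len(baselines)
    tp_shift = np.exp(
        rng.normal(0.0, cfg.timepoint_shift_sigma, (cfg.n_timepoints, n_genes))
    )
    blocks: list[sp.csc_matrix] = []
    meta_rows: list[tuple[str, int]] = []
    shape = 1.0 / cfg.nb_dispersion
    for type_name in type_names:
        effect = np.ones(n_genes)
        effect[programs[type_name]] = cfg.program_effect
        for tp in range(cfg.n_timepoints):
            n_cells = cfg.cells_per_type_per_timepoint
            lib = np.exp(
                rng.normal(0.0, cfg.libsize_lognormal_sigma, n_cells)
            )
            mu = (baselines * effect * tp_shift[tp])[:, None] * lib[None, :]
            lam = rng.gamma(shape, mu * cfg.nb_dispersion)
            counts = rng.poisson(lam)
            blocks.append(sp.csc_matrix(counts))
            meta_rows.extend((type_name, tp) for _ in range(n_cells))
    mat = sp.hstack(blocks, format="csc")
    meta = pd.DataFrame(meta_rows, columns=["cell_type", "timepoint"])
    return mat, meta


def generate_paired_datasets(
    config: SynthConfig,
) -> tuple[CountMatrix, CountMatrix, OrthologTable, SyntheticTruth]:
    """Generate a paired two-species dataset with known ground truth.

    Returns count matrices for species A and B, the ortholog table
    linking them, and the SyntheticTruth describing planted programs.
    One RNG stream per species, keyed by (seed, species index), makes
    output bit-reproducible regardless of call order.
    """
    cfg = config
    cfg.validate()
    rng_design = np.random.default_rng([cfg.seed, 2])
    rng_a = np.random.default_rng([cfg.seed, 0])
    rng_b = np.random.default_rng([cfg.seed, 1])

    g = cfg.genes_per_species
    genes_a = _gene_ids("GA", g)
    genes_b = _gene_ids("GB", g)

    # gene layout per species: [0, n11) 1:1 orthologs; on the A side
    # [n11, n11+n1m) map each to two B genes [n11, n11+2*n1m); the rest
    # are species-private, with the final genes reserved for mito/rRNA.
    n11, n1m = cfg.n_one2one, cfg.n_one2many
    n_covar = cfg.n_mito_genes + cfg.n_rrna_genes
    private_a = np.arange(n11 + n1m, g - n_covar)
    private_b = np.arange(n11 + 2 * n1m, g - n_covar)
    mito_idx = np.arange(g - n_covar, g - cfg.n_rrna_genes)
    rrna_idx = np.arange(g - cfg.n_rrna_genes, g)

    rows = [(genes_a[i], genes_b[i], "one2one") for i in range(n11)]
    for j in range(n1m):
        a = genes_a[n11 + j]
        rows.append((a, genes_b[n11 + 2 * j], "one2many"))
        rows.append((a, genes_b[n11 + 2 * j + 1], "one2many"))
    orthologs = OrthologTable(
        pd.DataFrame(rows, columns=["gene_A", "gene_B", "relation"])
    )

    # Shared baselines for 1:1 orthologs so that background expression is
    # comparable across species; independent baselines elsewhere.
    base_shared = np.exp(
        rng_design.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma, n11)
    )
    base_a = np.exp(
        rng_a.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma, g)
    )
    base_b = np.exp(
        rng_b.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma, g)
    )
    base_a[:n11] = base_shared
    base_b[:n11] = base_shared

    # Mito/rRNA genes sized so their expected share of transcripts per
    # cell matches the configured means.
    for base, rng in ((base_a, rng_a), (base_b, rng_b)):
        regular_total = base[: g - n_covar].sum()
        rest = 1.0 - cfg.mito_frac_mean - cfg.rrna_frac_mean
        for idx, frac in ((mito_idx, cfg.mito_frac_mean),
                          (rrna_idx, cfg.rrna_frac_mean)):
            if len(idx) == 0 or frac == 0:
                base[idx] = 1e-12  # strictly positive rate
                continue
            w = np.exp(rng.normal(0.0, 0.5, len(idx)))
            base[idx] = w / w.sum() * regular_total * frac / rest

    # --- programs ------------------------------------------------------
    shared_types = [f"shared_{t}" for t in range(cfg.n_types_shared)]
    a_types = [f"A_only_{t}" for t in range(cfg.n_types_specific_A)]
    b_types = [f"B_only_{t}" for t in range(cfg.n_types_specific_B)]

    pool11 = rng_design.permutation(n11)
    cursor = 0

    def take11(n: int) -> np.ndarray:
        nonlocal cursor
        out = pool11[cursor: cursor + n]
        cursor += n
        return out

    programs_a: dict[str, np.ndarray] = {}
    programs_b: dict[str, np.ndarray] = {}
    specificity: dict[str, str] = {}

    n_div = int(round(cfg.divergence_frac * cfg.program_size))
    for t in shared_types:
        prog = take11(cfg.program_size)
        prog_b = prog.copy()
        if n_div:
            prog_b[:n_div] = take11(n_div)  # rewired, still 1:1 space
        programs_a[t] = np.sort(prog)
        programs_b[t] = np.sort(prog_b)
        specificity[t] = "shared"

    n_on_orth = int(round(cfg.specific_ortholog_frac * cfg.program_size))
    priv_a = rng_design.permutation(private_a)
    priv_b = rng_design.permutation(private_b)
    pa = pb = 0
    for t in a_types:
        n_priv = min(cfg.program_size - n_on_orth, len(priv_a) - pa)
        orth_part = take11(cfg.program_size - n_priv)
        programs_a[t] = np.sort(
            np.concatenate([orth_part, priv_a[pa: pa + n_priv]])
        )
        pa += n_priv
        specificity[t] = "A_only"
    for t in b_types:
        n_priv = min(cfg.program_size - n_on_orth, len(priv_b) - pb)
        orth_part = take11(cfg.program_size - n_priv)
        programs_b[t] = np.sort(
            np.concatenate([orth_part, priv_b[pb: pb + n_priv]])
        )
        pb += n_priv
        specificity[t] = "B_only"

    types_a = shared_types + a_types
    types_b = shared_types + b_types

    counts_a, meta_a = _species_counts(cfg, rng_a, base_a, types_a, programs_a)
    counts_b, meta_b = _species_counts(cfg, rng_b, base_b, types_b, programs_b)
    meta_a["species"] = "A"
    meta_b["species"] = "B"

    cm_a = CountMatrix(
        counts_a, genes_a,
        [f"A-{i:05d}" for i in range(counts_a.shape[1])],
        sample_id="synthA", species="A", cell_meta=meta_a,
    )
    cm_b = CountMatrix(
        counts_b, genes_b,
        [f"B-{i:05d}" for i in range(counts_b.shape[1])],
        sample_id="synthB", species="B", cell_meta=meta_b,
    )

    programs = {
        **{("A", t): [genes_a[i] for i in programs_a[t]] for t in types_a},
        **{("B", t): [genes_b[i] for i in programs_b[t]] for t in types_b},
    }
    cell_table = pd.concat(
        [
            meta_a.assign(barcode=cm_a.barcodes),
            meta_b.assign(barcode=cm_b.barcodes),
        ],
        ignore_index=True,
    )
    truth = SyntheticTruth(
        programs=programs,
        specificity=specificity,
        mito_genes={
            "A": [genes_a[i] for i in mito_idx],
            "B": [genes_b[i] for i in mito_idx],
        },
        rrna_genes={
            "A": [genes_a[i] for i in rrna_idx],
            "B": [genes_b[i] for i in rrna_idx],
        },
        config=cfg,
        cell_table=cell_table,
    )
    return cm_a, cm_b, orthologs, truth


@dataclass
class BulkTriplet:
    """Bulk count vectors for a whole-embryo / cells / nuclei experiment."""

    embryo: np.ndarray
    cells: np.ndarray
    nuclei: np.ndarray
    bias_sigma_cells: float
    bias_sigma_nuclei: float
    gene_ids: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "embryo": self.embryo,
                "cells": self.cells,
                "nuclei": self.nuclei,
            },
            index=self.gene_ids or None,
        )


def generate_bulk_triplet(
    n_genes: int,
    bias_sigma_nuclei: float,
    bias_sigma_cells: float,
    seed: int,
    mean_depth: float = 500.0,
    baseline_log_sigma: float = 1.0,
    sampling_noise: bool = True,
) -> BulkTriplet:
    """Simulate one culture split into embryo / cells / nuclei aliquots.

    Per-gene expectations are log-normal; the cells and nuclei aliquots
    multiply each gene's expectation by ``2**Normal(0, sigma)`` — an
    isolation bias whose log2 standard deviation is the quantity the
    concordance analysis recovers — and all three vectors are then
    Poisson-sampled (``sampling_noise=False`` returns expectations,
    rounded to counts).
    """
    if n_genes < 2:
        raise ValueError("n_genes must be at least 2")
    if bias_sigma_nuclei < 0 or bias_sigma_cells < 0:
        raise ValueError("bias sigmas must be non-negative")
    rng = np.random.default_rng([seed, 3])
    log_mu = rng.normal(0.0, baseline_log_sigma, n_genes)
    mu = np.exp(log_mu)
    mu *= mean_depth * n_genes / mu.sum()

    mu_nuc = mu * 2.0 ** rng.normal(0.0, bias_sigma_nuclei, n_genes)
    mu_cell = mu * 2.0 ** rng.normal(0.0, bias_sigma_cells, n_genes)
    if sampling_noise:
        embryo = rng.poisson(mu).astype(float)
        nuclei = rng.poisson(mu_nuc).astype(float)
        cells = rng.poisson(mu_cell).astype(float)
    else:
        embryo, nuclei, cells = np.round(mu), np.round(mu_nuc), np.round(mu_cell)
    return BulkTriplet(
        embryo=embryo,
        cells=cells,
        nuclei=nuclei,
        bias_sigma_cells=bias_sigma_cells,
        bias_sigma_nuclei=bias_sigma_nuclei,
        gene_ids=_gene_ids("BG", n_genes),
    )
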