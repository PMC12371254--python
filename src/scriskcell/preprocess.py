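"""QC filtering, library-size log-normalization, and variance-based HVG selection.

The index model consumes log-normalized expression of highly variable genes.
Library-size totals are computed over the full gene set *before* any gene
selection, so feature selection cannot change per-cell scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Cohort


class EmptyCohortError(ValueError):
    """A QC filter removed every cell."""


@dataclass
class NormalizedMatrix:
    """Dense log-normalized expression (cells × selected genes)."""

    values: np.ndarray
    cell_ids: pd.Index
    gene_ids: pd.Index
    params: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("normalized values must be finite and non-negative")


def qc_filter(cohort: Cohort, min_genes_per_cell: int = 200,
              min_cells_per_gene: int = 3) -> Cohort:
    """Drop low-complexity cells, then rarely detected genes, in that order.

    A cell is kept when it detects (count > 0) at least ``min_genes_per_cell``
    genes; afterwards a gene is kept when detected in at least
    ``min_cells_per_gene`` of the surviving cells. Donors losing all cells are
    dropped from the donor table.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("QC thresholds must be >= 0")
    detected = cohort.counts.copy()
    detected.data = np.ones_like(detected.data)
    genes_per_cell = np.asarray(detected.sum(axis=1)).ravel()
    keep_cells = genes_per_cell >= min_genes_per_cell
    if not keep_cells.any():
        raise EmptyCohortError(
            f"min_genes_per_cell={min_genes_per_cell} removed all {cohort.n_cells} cells"
        )
    counts = cohort.counts[keep_cells]
    cells = cohort.cells.loc[keep_cells]

    det = counts.copy()
    det.data = np.ones_like(det.data)
    cells_per_gene = np.asarray(det.sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    if not keep_genes.any():
        raise EmptyCohortError(
            f"min_cells_per_gene={min_cells_per_gene} removed all genes"
        )
    counts = counts[:, keep_genes]
    genes = pd.Index(np.asarray(cohort.genes)[keep_genes], name="gene_id")
    donors = cohort.donors.loc[cohort.donors.index.isin(cells["donor_id"])]
    return Cohort(counts, cells.copy(), genes, donors.copy())


def normalize_log(cohort: Cohort, scale: float = 1e4) -> NormalizedMatrix:
    """ln(1 + scale * count / cell_total), totals over the full gene set.

    Raises ``ValueError`` for cells with zero total counts (run
    :func:`qc_filter` first).
    """
    totals = np.asarray(cohort.counts.sum(axis=1), dtype=np.float64).ravel()
    if np.any(totals == 0):
        zero = list(cohort.cell_ids[totals == 0][:5])
        raise ValueError(f"cells with zero total counts: {zero}")
    dense = np.asarray(cohort.counts.todense(), dtype=np.float64)
    values = np.log1p(dense * (scale / totals)[:, None])
    return NormalizedMatrix(values, cohort.cell_ids.copy(),
                            pd.Index(cohort.genes, name="gene_id"),
                            {"scale": float(scale), "log_base": "e", "hvg_n_top": None})


def select_hvg(norm: NormalizedMatrix, n_top: int) -> NormalizedMatrix:
    """Keep the ``n_top`` genes of highest variance (sample variance, ddof=1).

    Ties are broken by lexicographic gene id so selection is deterministic
    under any gene permutation; retained genes keep their original column
    order.
    """
    n_genes = norm.values.shape[1]
    if not 1 <= n_top <= n_genes:
        raise ValueError(f"n_top={n_top} outside [1, {n_genes}]")
    var = norm.values.var(axis=0, ddof=1) if norm.values.shape[0] > 1 else np.zeros(n_genes)
    # rank by (-variance, gene_id): lexicographic pre-sort + stable sort on -var
    lex = np.argsort(np.asarray(norm.gene_ids, dtype=object))
    ranked = lex[np.argsort(-var[lex], kind="stable")]
    keep = np.sort(ranked[:n_top])
    params = dict(norm.params, hvg_n_top=int(n_top))
    return NormalizedMatrix(norm.values[:, keep], norm.cell_ids,
                            pd.Index(np.asarray(norm.gene_ids)[keep], name="gene_id"),
                            params)
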