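"""Cohort container and I/O for multi-donor single-cell count data.

A :class:`Cohort` bundles a sparse cell×gene raw count matrix with two
metadata tables: a per-cell table (donor id, cell-type label) and a per-donor
table carrying the ordinal disease state (ND=0, preT2D=1, T2D=2) plus optional
clinical covariates (HbA1c %, BMI kg/m², C-peptide, age, sex). Counts are
always oriented cells-as-rows, genes-as-columns in memory; the Matrix Market
reader detects and fixes a transposed file from the sidecar table dimensions.
Missing covariates are carried as NaN (or pandas NA for sex) and are never
silently imputed to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

#: canonical disease-state encoding, ordinal along the ND → preT2D → T2D axis
STATE_CODES: dict[str, int] = {"ND": 0, "preT2D": 1, "T2D": 2}
STATE_LABELS: dict[int, str] = {v: k for k, v in STATE_CODES.items()}

#: numeric covariates recognized in donors.tsv (all optional)
NUMERIC_COVARIATES = ("hba1c", "bmi", "c_peptide", "age")


class CohortSchemaError(ValueError):
    """A required column is missing or a value cannot be interpreted."""


class CohortIntegrityError(ValueError):
    """Cross-table references are inconsistent (e.g. unknown donor)."""


@dataclass
class Cohort:
    """Validated cell×gene count cohort.

    Attributes
    ----------
    counts
        Sparse CSR matrix of raw counts, cells × genes, non-negative integers.
    cells
        DataFrame indexed by unique ``cell_id`` with columns ``donor_id`` and
        ``cell_type``; rows align with ``counts`` rows.
    genes
        Index of unique gene ids aligned with ``counts`` columns.
    donors
        DataFrame indexed by unique ``donor_id`` with integer column ``state``
        and optional covariate columns.
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.Index
    donors: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        data = self.counts.data
        if data.size and data.min() < 0:
            raise ValueError("counts contain negative entries")
        if data.size and not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts contain non-integer values")
            self.counts = self.counts.astype(np.int64)
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cells):
            raise CohortIntegrityError(
                f"count rows ({n_cells}) != cell table rows ({len(self.cells)})"
            )
        if n_genes != len(self.genes):
            raise CohortIntegrityError(
                f"count columns ({n_genes}) != gene ids ({len(self.genes)})"
            )
        if self.cells.index.has_duplicates:
            dups = self.cells.index[self.cells.index.duplicated()].unique().tolist()
            raise CohortIntegrityError(f"duplicate cell ids: {dups[:5]}")
        if pd.Index(self.genes).has_duplicates:
            raise CohortIntegrityError("duplicate gene ids")
        for col in ("donor_id", "cell_type"):
            if col not in self.cells.columns:
                raise CohortSchemaError(f"cell table missing column '{col}'")
        if "state" not in self.donors.columns:
            raise CohortSchemaError("donor table missing column 'state'")
        if self.donors.index.has_duplicates:
            raise CohortIntegrityError("duplicate donor ids")
        bad_states = set(self.donors["state"].unique()) - set(STATE_LABELS)
        if bad_states:
            raise CohortSchemaError(f"unknown state codes: {sorted(bad_states)}")
        unknown = set(self.cells["donor_id"]) - set(self.donors.index)
        if unknown:
            raise CohortIntegrityError(
                f"cells reference donors absent from donor table: {sorted(unknown)[:10]}"
            )
        unreferenced = set(self.donors.index) - set(self.cells["donor_id"])
        if unreferenced:
            raise CohortIntegrityError(
                f"donors with zero cells: {sorted(unreferenced)[:10]}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def cell_states(self) -> pd.Series:
        """Ordinal disease state of each cell's donor, aligned to cells."""
        return self.cells["donor_id"].map(self.donors["state"]).rename("state")

    def cell_types(self) -> list[str]:
        return sorted(self.cells["cell_type"].unique())

    def to_anndata(self):
        """Export to an :class:`anndata.AnnData` (cells × genes)."""
        import anndata as ad

        obs = self.cells.copy()
        obs["state"] = self.cell_states().map(STATE_LABELS)
        return ad.AnnData(X=self.counts.copy(), obs=obs,
                          var=pd.DataFrame(index=pd.Index(self.genes, name="gene_id")))


def subset_by_cell_type(cohort: Cohort, cell_type: str) -> Cohort:
    """Restrict a cohort to the cells of one type.

    The donor table is restricted to donors retaining at least one cell; the
    gene set is unchanged. Raises ``ValueError`` listing available types when
    ``cell_type`` does not occur.
    """
    mask = (cohort.cells["cell_type"] == cell_type).to_numpy()
    if not mask.any():
        raise ValueError(
            f"cell type {cell_type!r} not present; available: {cohort.cell_types()}"
        )
    cells = cohort.cells.loc[mask]
    donors = cohort.donors.loc[cohort.donors.index.isin(cells["donor_id"])]
    return Cohort(cohort.counts[mask], cells.copy(), cohort.genes, donors.copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_states(raw: pd.Series, aliases: dict[str, str] | None) -> pd.Series:
    mapping = dict(STATE_CODES)
    for alias, canon in (aliases or {}).items():
        if canon not in STATE_CODES:
            raise CohortSchemaError(f"alias {alias!r} maps to unknown state {canon!r}")
        mapping[alias] = STATE_CODES[canon]
    # already-coded integers pass through
    def one(v):
        if isinstance(v, (int, np.integer)):
            if int(v) in STATE_LABELS:
                return int(v)
            raise CohortSchemaError(f"unknown integer state code {v}")
        s = str(v)
        if s in mapping:
            code = mapping[s]
            return code if isinstance(code, int) else STATE_CODES[s]
        raise CohortSchemaError(
            f"unknown disease-state label {s!r}; accepted: {sorted(mapping)}"
        )

    return raw.map(one).astype(np.int64)


def _read_table(path: Path, required: tuple[str, ...], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{what} table {path} missing column(s) {missing}")
    return df


def load_cohort(
    counts_path: str | Path,
    cells_path: str | Path,
    donors_path: str | Path,
    genes_path: str | Path | None = None,
    state_aliases: dict[str, str] | None = None,
) -> Cohort:
    """Load a cohort from Matrix Market counts plus TSV sidecar tables.

    The matrix may be stored either cells×genes or transposed (10x
    convention); orientation is detected by matching the declared dimensions
    against the sidecar row counts, with cells×genes assumed for a square
    matrix. Donor rows with no cells are dropped (logged). State strings are
    mapped through :data:`STATE_CODES` plus any ``state_aliases``
    (alias → canonical label); unknown strings are rejected.
    """
    counts_path, cells_path, donors_path = map(Path, (counts_path, cells_path, donors_path))
    cells_raw = _read_table(cells_path, ("cell_id", "donor_id", "cell_type"), "cells")
    donors_raw = _read_table(donors_path, ("donor_id", "state"), "donors")

    mat = mmread(counts_path)
    n_cells = len(cells_raw)
    if genes_path is not None:
        genes = pd.Index(_read_table(Path(genes_path), ("gene_id",), "genes")["gene_id"])
        if mat.shape == (n_cells, len(genes)):
            pass
        elif mat.shape == (len(genes), n_cells):
            mat = mat.T
        else:
            raise CohortIntegrityError(
                f"matrix shape {mat.shape} matches neither (cells, genes)="
                f"({n_cells}, {len(genes)}) nor its transpose"
            )
    else:
        if mat.shape[0] == n_cells:
            pass
        elif mat.shape[1] == n_cells:
            mat = mat.T
        else:
            raise CohortIntegrityError(
                f"matrix shape {mat.shape} has no axis of length n_cells={n_cells}"
            )
        genes = pd.Index([f"g{j:05d}" for j in range(mat.shape[1])], name="gene_id")

    data = mat.tocsr().data
    if data.size and (np.any(data < 0) or not np.allclose(data, np.round(data))):
        raise ValueError(f"{counts_path}: counts must be non-negative integers")

    cells = cells_raw.set_index("cell_id")[["donor_id", "cell_type"]]
    donors = donors_raw.set_index("donor_id")
    donors["state"] = _parse_states(donors["state"], state_aliases)
    for cov in NUMERIC_COVARIATES:
        if cov in donors.columns:
            donors[cov] = pd.to_numeric(donors[cov], errors="coerce")
    if "sex" in donors.columns:
        donors["sex"] = donors["sex"].astype("string")

    unknown = set(cells["donor_id"]) - set(donors.index)
    if unknown:
        raise CohortIntegrityError(
            f"cells reference donors absent from donor table: {sorted(unknown)[:10]}"
        )
    unreferenced = donors.index.difference(pd.Index(cells["donor_id"].unique()))
    if len(unreferenced):
        logger.info("dropping %d donor(s) with zero cells: %s",
                    len(unreferenced), list(unreferenced[:10]))
        donors = donors.drop(index=unreferenced)

    return Cohort(mat.tocsr().astype(np.int64), cells, genes, donors)


def load_cohort_dir(directory: str | Path, **kwargs) -> Cohort:
    """Load ``matrix.mtx`` / ``cells.tsv`` / ``genes.tsv`` / ``donors.tsv`` from one directory."""
    d = Path(directory)
    genes = d / "genes.tsv"
    return load_cohort(d / "matrix.mtx", d / "cells.tsv", d / "donors.tsv",
                       genes_path=genes if genes.exists() else None, **kwargs)


def load_cohort_h5ad(path: str | Path, donors: pd.DataFrame | str | Path,
                     state_aliases: dict[str, str] | None = None) -> Cohort:
    """Load cells×genes counts from an AnnData .h5ad file plus a donor table.

    ``adata.obs`` must carry ``donor_id`` and ``cell_type``; ``adata.X`` must
    hold raw counts.
    """
    import anndata as ad

    adata = ad.read_h5ad(path)
    for col in ("donor_id", "cell_type"):
        if col not in adata.obs.columns:
            raise CohortSchemaError(f"h5ad obs missing column '{col}'")
    cells = adata.obs[["donor_id", "cell_type"]].astype(str)
    cells.index.name = "cell_id"
    if not isinstance(donors, pd.DataFrame):
        donors = _read_table(Path(donors), ("donor_id", "state"), "donors").set_index("donor_id")
    donors = donors.copy()
    donors["state"] = _parse_states(donors["state"], state_aliases)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(np.asarray(adata.X))
    return Cohort(X.tocsr().astype(np.int64), cells,
                  pd.Index(adata.var_names, name="gene_id"), donors)


def save_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write matrix.mtx, cells.tsv, genes.tsv, donors.tsv; returns the paths.

    Output is byte-deterministic for a given cohort (no timestamps).
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": d / "matrix.mtx",
        "cells": d / "cells.tsv",
        "genes": d / "genes.tsv",
        "donors": d / "donors.tsv",
    }
    mmwrite(paths["matrix"], cohort.counts.tocoo(), field="integer")
    cells = cohort.cells.reset_index()
    cells.columns = ["cell_id", "donor_id", "cell_type"]
    cells.to_csv(paths["cells"], sep="\t", index=False)
    pd.DataFrame({"gene_id": list(cohort.genes)}).to_csv(paths["genes"], sep="\t", index=False)
    donors = cohort.donors.copy()
    donors["state"] = donors["state"].map(STATE_LABELS)
    donors.reset_index(names="donor_id").to_csv(paths["donors"], sep="\t", index=False)
    return paths
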