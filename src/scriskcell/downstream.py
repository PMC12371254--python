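"""Risk-vs-nonrisk pseudobulk differential expression and subtype dynamics.

Pseudobulk DE sums raw counts per donor × compartment (risk / nonrisk) and
tests each gene with a negative-binomial Wald test: median-of-ratios size
factors, method-of-moments dispersion, and a log-linear mean model with donor
and compartment terms (paired design, since both compartments come from the
same donors), BH-corrected across tested genes. This is a deliberately
minimal replicate-level NB test, not a full shrinkage-based DE stack.

Subtype dynamics clusters the cells (PCA → kNN graph → Louvain community
detection) and, per cluster and disease stage, quantifies risk-cell
enrichment with a hypergeometric tail test, BH-corrected across clusters
within each stage.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data_model import Cohort, CohortIntegrityError, STATE_LABELS
from .preprocess import NormalizedMatrix
from .staging_assoc import bh_adjust

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


class EmptyDesignError(ValueError):
    """No donor retains both compartments after the min-cells filter."""


@dataclass
class PseudobulkMatrix:
    """Summed raw counts per (donor, compartment) sample."""

    counts: pd.DataFrame          # rows: MultiIndex (donor_id, compartment); cols: genes
    n_cells: pd.Series            # per sample
    excluded: list                # (donor, reason) samples dropped by the pairing rule


def pseudobulk_aggregate(cohort: Cohort, risk: pd.DataFrame,
                         min_cells: int = 10) -> PseudobulkMatrix:
    """Sum raw counts per donor × {risk, nonrisk} compartment.

    A donor is kept only when *both* compartments contain at least
    ``min_cells`` cells (paired design); dropped donors are recorded in
    ``excluded``. Raises :class:`EmptyDesignError` when no donor survives.
    """
    unknown = set(risk["cell_id"]) - set(cohort.cell_ids)
    if unknown:
        raise CohortIntegrityError(
            f"risk calls reference unknown cells: {sorted(unknown)[:10]}"
        )
    is_risk = risk.set_index("cell_id")["is_risk"].reindex(cohort.cell_ids)
    covered = is_risk.notna().to_numpy()
    donor = cohort.cells["donor_id"].to_numpy()
    comp = np.where(is_risk.fillna(False).to_numpy(), "risk", "nonrisk")

    keys = pd.MultiIndex.from_arrays([donor[covered], comp[covered]],
                                     names=["donor_id", "compartment"])
    uniq = keys.unique().sort_values()
    code = pd.Series(range(len(uniq)), index=uniq)
    rows = code.loc[keys].to_numpy()
    ind = sp.csr_matrix((np.ones(len(rows)), (rows, np.flatnonzero(covered))),
                        shape=(len(uniq), cohort.n_cells))
    sums = np.asarray((ind @ cohort.counts).todense(), dtype=np.int64)
    n_cells = pd.Series(np.asarray(ind.sum(axis=1)).ravel().astype(int), index=uniq)

    excluded = []
    keep_donors = []
    for d in sorted(set(uniq.get_level_values(0))):
        ok = all((d, c) in n_cells.index and n_cells[(d, c)] >= min_cells
                 for c in ("risk", "nonrisk"))
        if ok:
            keep_donors.append(d)
        else:
            excluded.append((d, "compartment below min_cells"))
            logger.info("pseudobulk: dropping donor %s (compartment < %d cells)", d, min_cells)
    if not keep_donors:
        raise EmptyDesignError(
            f"no donor has >= {min_cells} cells in both compartments"
        )
    keep = uniq.get_level_values(0).isin(keep_donors)
    counts = pd.DataFrame(sums[keep], index=uniq[keep], columns=list(cohort.genes))
    return PseudobulkMatrix(counts, n_cells[keep], excluded)


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors (genes with any zero skipped)."""
    logc = np.log(counts, out=np.full(counts.shape, -np.inf), where=counts > 0)
    loggeo = logc.mean(axis=0)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError("no gene is expressed in every sample; cannot derive size factors")
    logratio = logc[:, usable] - loggeo[usable]
    return np.exp(np.median(logratio, axis=1))


def de_test(pb: PseudobulkMatrix) -> pd.DataFrame:
    """Per-gene NB Wald test of the risk-vs-nonrisk compartment effect.

    Returns one row per tested gene: gene_id, log2fc (risk over nonrisk),
    p, p_adj, mean_expr_risk, mean_expr_nonrisk (means of size-factor
    normalized counts). Genes with zero counts in every sample are skipped
    and reported in the ``skipped_genes`` DataFrame attr. Requires ≥2 donors
    with both compartments.
    """
    donors = pb.counts.index.get_level_values("donor_id")
    comps = pb.counts.index.get_level_values("compartment")
    donor_ids = sorted(set(donors))
    if len(donor_ids) < 2:
        raise ValueError(f"de_test needs >=2 complete donor pairs, have {len(donor_ids)}")

    Y = pb.counts.to_numpy(dtype=np.float64)
    sf = _size_factors(Y)
    offset = np.log(sf)
    is_risk = (comps == "risk").astype(float)
    donor_dummies = pd.get_dummies(pd.Series(donors), drop_first=True, dtype=float).to_numpy()
    X = np.column_stack([np.ones(len(Y)), donor_dummies, is_risk])

    q = Y / sf[:, None]
    m = q.mean(axis=0)
    v = q.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.clip((v - m) / np.square(m), 1e-8, 10.0)

    nonzero = m > 0
    skipped = pd.DataFrame({"gene_id": pb.counts.columns[~nonzero]})
    rows = []
    for j in np.flatnonzero(nonzero):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fam = sm.families.NegativeBinomial(alpha=float(alpha[j]))
                res = sm.GLM(Y[:, j], X, family=fam, offset=offset).fit(maxiter=100)
            beta = float(res.params[-1])
            pval = float(res.pvalues[-1])
            if not np.isfinite(pval):
                pval = 1.0
        except Exception:      # non-convergence on a degenerate gene
            beta, pval = 0.0, 1.0
        rows.append({"gene_id": pb.counts.columns[j],
                     "log2fc": beta / LN2, "p": pval,
                     "mean_expr_risk": float(q[is_risk == 1, j].mean()),
                     "mean_expr_nonrisk": float(q[is_risk == 0, j].mean())})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["skipped_genes"] = skipped
    out.attrs["size_factors"] = pd.Series(sf, index=pb.counts.index)
    return out


def subtype_cluster(norm: NormalizedMatrix, n_neighbors: int = 15, n_pcs: int = 30,
                    resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """PCA → kNN graph → Louvain communities; deterministic given the seed.

    Cluster ids are relabeled 0..k−1 by decreasing size (ties by first
    occurrence). Requires at least ``n_neighbors + 1`` cells.
    """
    n = norm.values.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need >= n_neighbors+1 = {n_neighbors + 1} cells, have {n}")
    n_comp = int(min(n_pcs, n - 1, norm.values.shape[1]))
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    emb = pca.fit_transform(norm.values)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    graph = ig.Graph(n=n, edges=sorted(edges))
    random.seed(seed)                      # igraph draws from Python's RNG
    part = graph.community_multilevel(resolution=resolution)
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()   # sorted desc, ties by first seen
    remap = {old: new for new, old in enumerate(sizes.index)}
    return pd.Series([remap[l] for l in labels], index=norm.cell_ids, name="cluster")


def risk_aggregation_dynamics(clusters: pd.Series, risk: pd.DataFrame,
                              cohort: Cohort) -> pd.DataFrame:
    """Risk-cell fraction and enrichment per (cluster, disease stage).

    Enrichment p is the hypergeometric upper tail of the cluster's risk count
    against the stage-wide risk rate, BH-adjusted across clusters within each
    stage. ``clusters`` and ``risk`` must cover the same cells.
    """
    risk_by_cell = risk.set_index("cell_id")["is_risk"]
    if set(clusters.index) != set(risk_by_cell.index):
        raise CohortIntegrityError("clusters and risk calls cover different cell sets")
    cells = pd.DataFrame({
        "cluster": clusters,
        "is_risk": risk_by_cell.reindex(clusters.index).astype(bool),
        "stage": clusters.index.map(cohort.cells["donor_id"]).map(cohort.donors["state"]),
    })
    if cells["stage"].isna().any():
        raise CohortIntegrityError("clustered cells not found in cohort")

    rows = []
    for stage, stage_df in cells.groupby("stage", sort=True):
        M = len(stage_df)
        K = int(stage_df["is_risk"].sum())
        stage_rows = []
        for cluster, cl_df in stage_df.groupby("cluster", sort=True):
            N = len(cl_df)
            k = int(cl_df["is_risk"].sum())
            p = float(stats.hypergeom.sf(k - 1, M, K, N))
            stage_rows.append({"cluster": cluster, "stage": STATE_LABELS[int(stage)],
                               "n_cells": N, "n_risk": k,
                               "risk_fraction": k / N, "p": min(p, 1.0)})
        padj = bh_adjust([r["p"] for r in stage_rows])
        for r, pa in zip(stage_rows, padj):
            r["p_adj"] = pa
        rows.extend(stage_rows)
    return pd.DataFrame(rows)
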