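"""Multi-donor single-cell count simulator with planted risk-cell programs.

The generator emulates the cohort structure the risk-cell framework assumes:
each donor carries a mixture of normal and disease-perturbed cells, with the
perturbed (risk) fraction increasing along the ND → preT2D → T2D continuum.
Gene baseline log-means are drawn once per run (normal, mean log 0.5, sd 1);
each donor adds an i.i.d. per-gene offset (donor signature); risk cells have a
fixed set of perturbed genes shifted by ``effect_log2fc`` log2-units; counts
are negative-binomial with mean m·libsize_factor and variance m + α·m²
(dispersion α). Risk status is i.i.d. Bernoulli within donor at the state's
configured rate, so realized donor fractions vary binomially around the
targets. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import Cohort, STATE_CODES, STATE_LABELS, save_cohort

_DONOR_PREFIX = {0: "ND", 1: "PRE", 2: "T2D"}

#: covariate generators per state: (hba1c mean/sd, bmi mean/sd, cpep mean/sd)
_COVARIATE_PARAMS = {
    0: {"hba1c": (5.4, 0.3), "bmi": (26.0, 4.0), "c_peptide": (2.2, 0.6)},
    1: {"hba1c": (6.0, 0.3), "bmi": (29.0, 4.5), "c_peptide": (1.8, 0.6)},
    2: {"hba1c": (7.5, 1.0), "bmi": (31.0, 5.0), "c_peptide": (1.2, 0.5)},
}


@dataclass
class SimConfig:
    """Simulation parameters; defaults define the reference study conditions."""

    n_donors: dict = field(default_factory=lambda: {"ND": 10, "preT2D": 10, "T2D": 10})
    cells_per_donor: int = 200
    n_genes: int = 1000
    n_perturbed_genes: int = 100
    effect_log2fc: float = 1.0
    risk_fraction: dict = field(default_factory=lambda: {"ND": 0.05, "preT2D": 0.15, "T2D": 0.30})
    nb_dispersion: float = 0.5
    donor_effect_sd: float = 0.15
    libsize_sd: float = 0.3
    cell_type: str = "beta"
    simulate_covariates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cells_per_donor", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_perturbed_genes <= self.n_genes:
            raise ValueError("n_perturbed_genes must be in [0, n_genes]")
        for label in STATE_CODES:
            if label not in self.n_donors:
                raise ValueError(f"n_donors missing state '{label}'")
            if label not in self.risk_fraction:
                raise ValueError(f"risk_fraction missing state '{label}'")
            f = self.risk_fraction[label]
            if not 0 <= f <= 1:
                raise ValueError(f"risk_fraction[{label}]={f} outside [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name in ("donor_effect_sd", "libsize_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    cell_truth: pd.DataFrame        # index cell_id, column is_risk_true
    perturbed_genes: list
    donor_truth: pd.DataFrame       # index donor_id: true_risk_fraction (realized), target
    gene_baseline: pd.Series | None = None   # baseline log-mean per gene (in-memory only)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean m, variance m + α m²); α → 0 degenerates to Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, SimTruth]:
    """Draw a cohort and its ground truth from the planted mixture model."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = pd.Index([f"g{j:05d}" for j in range(cfg.n_genes)], name="gene_id")
    base_logmean = rng.normal(np.log(0.5), 1.0, cfg.n_genes)
    perturbed = np.sort(rng.choice(cfg.n_genes, cfg.n_perturbed_genes, replace=False))
    shift = np.zeros(cfg.n_genes)
    shift[perturbed] = cfg.effect_log2fc * np.log(2.0)

    blocks, cell_rows, donor_rows = [], [], []
    for label, code in STATE_CODES.items():
        for d in range(cfg.n_donors[label]):
            donor_id = f"{_DONOR_PREFIX[code]}{d:02d}"
            donor_offset = rng.normal(0.0, cfg.donor_effect_sd, cfg.n_genes)
            is_risk = rng.random(cfg.cells_per_donor) < cfg.risk_fraction[label]
            lib = np.exp(rng.normal(0.0, cfg.libsize_sd, cfg.cells_per_donor))
            logmean = base_logmean + donor_offset
            means = np.exp(logmean[None, :] + np.outer(is_risk.astype(float), shift))
            means = means * lib[:, None]
            blocks.append(_nb_draw(rng, means, cfg.nb_dispersion))
            donor_rows.append({"donor_id": donor_id, "state": code,
                               "true_risk_fraction": float(is_risk.mean()),
                               "target_risk_fraction": cfg.risk_fraction[label]})
            for j in range(cfg.cells_per_donor):
                cell_rows.append({"cell_id": f"{donor_id}_c{j:04d}",
                                  "donor_id": donor_id,
                                  "cell_type": cfg.cell_type,
                                  "is_risk_true": bool(is_risk[j])})

    counts = sp.csr_matrix(np.vstack(blocks).astype(np.int64))
    cells_df = pd.DataFrame(cell_rows).set_index("cell_id")
    donors_df = pd.DataFrame(donor_rows).set_index("donor_id")

    donors = donors_df[["state"]].copy()
    if cfg.simulate_covariates:
        for cov in ("hba1c", "bmi", "c_peptide"):
            vals = np.array([
                rng.normal(*_COVARIATE_PARAMS[s][cov]) for s in donors["state"]
            ])
            donors[cov] = np.round(vals, 2)
        donors["age"] = rng.integers(25, 75, len(donors)).astype(float)
        donors["sex"] = pd.array(rng.choice(["M", "F"], len(donors)), dtype="string")
        # C-peptide is sparsely measured in real cohorts; drop half at random
        miss = rng.random(len(donors)) < 0.5
        donors.loc[miss, "c_peptide"] = np.nan

    cohort = Cohort(counts, cells_df[["donor_id", "cell_type"]], gene_ids, donors)
    truth = SimTruth(
        cell_truth=cells_df[["is_risk_true"]].copy(),
        perturbed_genes=list(gene_ids[perturbed]),
        donor_truth=donors_df[["state", "true_risk_fraction", "target_risk_fraction"]].copy(),
        gene_baseline=pd.Series(base_logmean, index=gene_ids, name="log_mean"),
    )
    return cohort, truth


def write_cohort(cohort: Cohort, truth: SimTruth | None, directory: str | Path) -> dict:
    """Write cohort files plus truth.tsv / perturbed_genes.tsv; byte-deterministic."""
    d = Path(directory)
    try:
        paths = save_cohort(cohort, d)
    except OSError as err:
        raise OSError(f"cannot write cohort to {d}: {err}") from err
    if truth is not None:
        truth_path = d / "truth.tsv"
        truth.cell_truth.reset_index(names="cell_id").to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        pg = d / "perturbed_genes.tsv"
        pd.DataFrame({"gene_id": truth.perturbed_genes}).to_csv(pg, sep="\t", index=False)
        paths["perturbed_genes"] = pg
        dt = d / "donor_truth.tsv"
        out = truth.donor_truth.copy()
        out["state"] = out["state"].map(STATE_LABELS)
        out.reset_index(names="donor_id").to_csv(dt, sep="\t", index=False)
        paths["donor_truth"] = dt
    return paths


def load_truth(directory: str | Path) -> SimTruth:
    """Reload the ground-truth tables written by :func:`write_cohort`."""
    d = Path(directory)
    cell_truth = pd.read_csv(d / "truth.tsv", sep="\t").set_index("cell_id")
    cell_truth["is_risk_true"] = cell_truth["is_risk_true"].astype(bool)
    perturbed = pd.read_csv(d / "perturbed_genes.tsv", sep="\t")["gene_id"].tolist()
    donor_truth = pd.read_csv(d / "donor_truth.tsv", sep="\t").set_index("donor_id")
    donor_truth["state"] = donor_truth["state"].map(STATE_CODES)
    return SimTruth(cell_truth, perturbed, donor_truth)
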