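"""Shared fixtures: hand-built toy cohorts and session-scoped simulation runs."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from scriskcell.data_model import Cohort
from scriskcell.pipeline import run_core
from scriskcell.synthetic_cohort import SimConfig, simulate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_cohort(counts, donor_of, cell_type="beta", states=None, genes=None):
    """Build a small validated cohort from dense counts and donor assignments."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = [f"c{i:03d}" for i in range(n_cells)]
    donor_of = list(donor_of)
    types = [cell_type] * n_cells if isinstance(cell_type, str) else list(cell_type)
    cells = pd.DataFrame({"donor_id": donor_of, "cell_type": types},
                         index=pd.Index(cell_ids, name="cell_id"))
    donor_ids = sorted(set(donor_of))
    if states is None:
        states = {d: i % 3 for i, d in enumerate(donor_ids)}
    donors = pd.DataFrame({"state": [states[d] for d in donor_ids]},
                          index=pd.Index(donor_ids, name="donor_id"))
    gene_index = pd.Index(genes if genes is not None
                          else [f"g{j:03d}" for j in range(n_genes)], name="gene_id")
    return Cohort(sp.csr_matrix(counts.astype(np.int64)), cells, gene_index, donors)


@pytest.fixture(scope="session")
def small_sim():
    """A fast cohort: 4/2/4 donors, 60 cells each, 150 genes, planted program."""
    cfg = SimConfig(n_donors={"ND": 4, "preT2D": 2, "T2D": 4}, cells_per_donor=60,
                    n_genes=150, n_perturbed_genes=30, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The reference study conditions (seed 1)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full analysis of the reference cohort: index → window call → staging."""
    cohort, truth = default_sim
    res = run_core(cohort, truth, seed=1,
                   stages=("qc", "index", "call", "stage", "associate"))
    return res, truth
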