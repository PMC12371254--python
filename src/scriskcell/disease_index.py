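"""Per-cell pseudo disease-state index learned from donor-level labels.

Each cell of a given type receives an index in [0, 1] ranking it along the
healthy → diseased continuum. The scorer is an elastic-net-regularized
binomial linear model on log-normalized HVG expression; cells inherit their
donor's endpoint state (ND=0, T2D=1) as the training label. Because those
labels are donor-level proxies — a diseased donor carries a mixture of normal
and perturbed cells — evaluation and scoring use donor-grouped
cross-validation: a cell is only ever scored by a model whose training set
excluded its donor, which blocks donor-signature leakage. Cells of
intermediate states (preT2D) never contribute to training and are scored by
averaging the fold models, so their placement on the continuum is a genuine
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data_model import Cohort, STATE_LABELS, subset_by_cell_type
from .preprocess import NormalizedMatrix, normalize_log, select_hvg


@dataclass
class IndexModelConfig:
    """Hyperparameters of the per-cell-type index model.

    n_folds must not exceed the donor count of either endpoint state.
    ``regularization_strength`` multiplies the elastic-net penalty relative to
    the weight-normalized log-loss (sample weights sum to 1); ``l1_ratio``
    mixes lasso (1.0) and ridge (0.0) parts. ``training_states`` are the
    ordinal endpoints used as class labels; all other states are score-only.
    """

    n_folds: int = 5
    regularization_strength: float = 2.0
    l1_ratio: float = 0.0
    seed: int = 0
    training_states: tuple[int, int] = (0, 2)
    solver_tol: float = 1e-5
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.regularization_strength <= 0:
            raise ValueError("regularization_strength must be > 0")
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError("l1_ratio must be in [0, 1]")


@dataclass
class IndexResult:
    """Per-cell indexes with fold provenance.

    ``table`` has one row per cell of the analyzed type: cell_id, cell_type,
    index, fold (the fold whose held-out set contained the cell; −1 for cells
    of non-endpoint states scored by fold-averaging). ``donor_folds`` maps each
    endpoint donor to its fold.
    """

    table: pd.DataFrame
    donor_folds: dict[str, int]
    config: IndexModelConfig
    feature_genes: pd.Index = field(default=None)
    fold_models: list = field(default=None, repr=False)


def assign_donor_folds(cohort: Cohort, n_folds: int, seed: int,
                       training_states: tuple[int, int] = (0, 2)) -> dict[str, int]:
    """Split endpoint donors into folds, stratified by state.

    Within each endpoint state the donors are shuffled (deterministically from
    ``seed``) and dealt round-robin, so per-state fold sizes differ by at most
    one and no donor appears in two folds.
    """
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    for state in training_states:
        donors = sorted(cohort.donors.index[cohort.donors["state"] == state])
        if len(donors) < n_folds:
            raise ValueError(
                f"state {STATE_LABELS.get(state, state)} has {len(donors)} donors, "
                f"fewer than n_folds={n_folds}"
            )
        order = rng.permutation(len(donors))
        for i, j in enumerate(order):
            folds[donors[j]] = i % n_folds
    return folds


class IndexScorer:
    """Fitted scorer: internal feature standardization + elastic-net logistic model.

    Features are standardized with the training mean/sd (sd floored at 1e-8)
    before both fitting and scoring; this conditions the solver and makes the
    penalty scale-free across genes. ``predict_proba(X)[:, 1]`` is the index.
    """

    def __init__(self, model: LogisticRegression, mean: np.ndarray, sd: np.ndarray):
        self.model = model
        self.mean = mean
        self.sd = sd

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64) - self.mean) / self.sd
        return self.model.predict_proba(Z)

    @property
    def coef_(self) -> np.ndarray:
        return self.model.coef_


def fit_index_model(X: np.ndarray, y: np.ndarray, cfg: IndexModelConfig) -> IndexScorer:
    """Fit the elastic-net binomial scorer on training cells.

    Class imbalance is handled by inverse-frequency sample weights normalized
    to sum 1, which also makes the fitted objective invariant under
    duplicating the training set. Returns a fitted :class:`IndexScorer`.
    """
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training set contains a single class ({classes.tolist()})")
    X = np.asarray(X, dtype=np.float64)
    n = len(y)
    mean = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-8)
    counts = np.bincount(y, minlength=2)
    # balanced weights summing to n, with C = 1/(reg*n): the fitted objective is
    # (mean inverse-frequency-weighted log-loss) + reg * elastic-net penalty,
    # hence invariant under duplicating the training set
    weights = n / (2.0 * counts[y])
    model = LogisticRegression(
        solver="saga",
        l1_ratio=cfg.l1_ratio,
        C=1.0 / (cfg.regularization_strength * n),
        tol=cfg.solver_tol,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    model.fit((X - mean) / sd, y, sample_weight=weights)
    return IndexScorer(model, mean, sd)


def compute_disease_index(
    cohort: Cohort,
    cell_type: str,
    cfg: IndexModelConfig | None = None,
    scale: float = 1e4,
    n_hvg: int = 2000,
    norm: NormalizedMatrix | None = None,
) -> IndexResult:
    """Score every cell of ``cell_type`` with a donor-grouped out-of-fold index.

    Endpoint-state cells are scored only by the fold model trained without
    their donor; non-endpoint cells get the mean of all fold models' scores.
    Cells are processed in canonical (sorted cell id) order internally, so the
    result is invariant to the input row ordering.

    Parameters
    ----------
    norm
        Optional precomputed log-normalized matrix for the cells of this type
        (rows must cover exactly those cells); when omitted it is computed
        with ``scale`` and ``min(n_hvg, n_genes)`` HVGs.
    """
    cfg = cfg or IndexModelConfig()
    sub = subset_by_cell_type(cohort, cell_type)
    if norm is None:
        norm = normalize_log(sub, scale=scale)
        norm = select_hvg(norm, min(n_hvg, len(norm.gene_ids)))
    elif set(norm.cell_ids) != set(sub.cell_ids):
        raise ValueError("provided norm does not cover exactly the cells of this type")

    # canonical ordering: sorted cell id
    order = np.argsort(np.asarray(norm.cell_ids, dtype=object))
    X = np.asarray(norm.values, dtype=np.float64)[order]
    cell_ids = pd.Index(np.asarray(norm.cell_ids)[order])
    donor_of = sub.cells["donor_id"].reindex(cell_ids)
    state_of = donor_of.map(sub.donors["state"]).to_numpy()

    lo, hi = cfg.training_states
    try:
        donor_folds = assign_donor_folds(sub, cfg.n_folds, cfg.seed, cfg.training_states)
    except ValueError as err:
        raise ValueError(f"[cell_type={cell_type}] {err}") from err
    cell_fold = donor_of.map(donor_folds).fillna(-1).astype(int).to_numpy()
    is_endpoint = np.isin(state_of, (lo, hi))
    y = (state_of == hi).astype(int)

    index = np.zeros(len(cell_ids))
    offfold_sum = np.zeros(len(cell_ids))
    models = []
    for f in range(cfg.n_folds):
        train = is_endpoint & (cell_fold != f)
        try:
            model = fit_index_model(X[train], y[train], cfg)
        except ValueError as err:
            raise ValueError(f"[cell_type={cell_type}, fold={f}] {err}") from err
        models.append(model)
        scores = model.predict_proba(X)[:, 1]
        held = is_endpoint & (cell_fold == f)
        index[held] = scores[held]
        offfold_sum += scores
    index[~is_endpoint] = offfold_sum[~is_endpoint] / cfg.n_folds
    index = np.clip(index, 0.0, 1.0)

    table = pd.DataFrame({
        "cell_id": cell_ids,
        "cell_type": cell_type,
        "index": index,
        "fold": np.where(is_endpoint, cell_fold, -1),
    }).reset_index(drop=True)
    return IndexResult(table, donor_folds, cfg, norm.gene_ids, models)
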