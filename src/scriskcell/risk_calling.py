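"""Convert sorted pseudo-indexes into binary risk-cell labels.

Three calling modes are provided: a fixed index cutoff (default 0.89, with the
strict ``index > threshold`` rule), an empirical-quantile cutoff pooled over
all cells of the type, and a sliding-window scan that picks the cutoff
maximizing donor-level separation of risk proportions across disease states
(Kruskal–Wallis statistic), subject to a minimum overall risk fraction. A
threshold-sensitivity table reports per-state mean proportions and pairwise
staging AUCs along a cutoff grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Cohort, STATE_LABELS


def _as_index_table(indexes) -> pd.DataFrame:
    df = indexes.table if hasattr(indexes, "table") else indexes
    for col in ("cell_id", "index"):
        if col not in df.columns:
            raise ValueError(f"index table missing column '{col}'")
    return df


def _make_calls(df: pd.DataFrame, threshold: float, method: str) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": df["cell_id"].to_numpy(),
        "is_risk": df["index"].to_numpy() > threshold,
        "threshold": float(threshold),
        "method": method,
        "cell_type": df["cell_type"].to_numpy() if "cell_type" in df else "",
    })


def call_risk_fixed(indexes, threshold: float = 0.89) -> pd.DataFrame:
    """Flag cells with index strictly greater than a fixed threshold in [0, 1]."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return _make_calls(_as_index_table(indexes), threshold, "fixed")


def call_risk_quantile(indexes, q: float) -> pd.DataFrame:
    """Flag cells above the empirical q-quantile of the pooled index.

    The quantile uses linear interpolation (numpy default). With degenerate
    all-equal indexes the strict-greater rule flags no cells and a warning is
    emitted.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q={q} outside (0, 1)")
    df = _as_index_table(indexes)
    if len(df) < 2:
        raise ValueError("quantile calling needs at least 2 cells")
    values = df["index"].to_numpy()
    threshold = float(np.quantile(values, q, method="linear"))
    if np.ptp(values) == 0:
        warnings.warn("all indexes equal; quantile calling flags no cells")
    return _make_calls(df, threshold, "quantile")


@dataclass
class SlidingWindowResult:
    threshold: float
    calls: pd.DataFrame
    trace: pd.DataFrame  # one row per candidate: threshold, statistic, risk_fraction, feasible


def _donor_proportions_at(calls_risk: np.ndarray, donor_of: np.ndarray,
                          donor_index: pd.Index) -> pd.Series:
    risk = pd.Series(calls_risk).groupby(pd.Series(donor_of)).mean()
    return risk.reindex(donor_index)


def call_risk_sliding_window(
    indexes,
    cohort: Cohort,
    grid: np.ndarray | None = None,
    min_risk_fraction: float = 0.01,
    cut_low: float = 0.10,
    cut_high: float = 0.20,
) -> SlidingWindowResult:
    """Scan candidate thresholds; keep the one best reproducing the stage bands.

    For each grid value, per-donor risk proportions are computed and scored by
    (a) the rule-band staging accuracy — the fraction of donors whose
    proportion falls in the band of their true state (< ``cut_low`` → ND,
    [``cut_low``, ``cut_high``] → preT2D, > ``cut_high`` → T2D) — and (b) the
    Kruskal–Wallis statistic of proportions across disease-state groups.
    Among candidates whose overall risk fraction is at least
    ``min_risk_fraction`` (guarding the degenerate flag-nothing optimum), the
    accuracy maximizer wins; accuracy ties are broken by the Kruskal–Wallis
    statistic, remaining ties by the largest threshold. Accuracy is the
    primary criterion because the band cutoffs are part of the staging rule:
    a rank-only criterion would accept any monotone recalibration of the
    proportions, while downstream staging needs them on the band scale.
    Requires at least two disease states among the donors of the indexed
    cells.
    """
    df = _as_index_table(indexes)
    if grid is None:
        grid = np.round(np.linspace(0.01, 0.99, 99), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("grid must be non-empty and within [0, 1]")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")

    donor_of = df["cell_id"].map(cohort.cells["donor_id"])
    if donor_of.isna().any():
        raise ValueError("index table contains cells unknown to the cohort")
    donor_state = cohort.donors["state"]
    states_present = sorted(donor_state.loc[donor_of.unique()].unique())
    if len(states_present) < 2:
        raise ValueError(
            f"sliding-window calling needs >=2 disease states, found "
            f"{[STATE_LABELS[s] for s in states_present]}"
        )

    values = df["index"].to_numpy()
    donors = pd.Index(sorted(donor_of.unique()))
    groups_of = donor_state.reindex(donors).to_numpy()
    rows = []
    for t in grid:
        is_risk = values > t
        frac = float(is_risk.mean())
        props = _donor_proportions_at(is_risk, donor_of.to_numpy(), donors).to_numpy()
        staged = np.where(props < cut_low, 0, np.where(props <= cut_high, 1, 2))
        accuracy = float((staged == groups_of).mean())
        samples = [props[groups_of == s] for s in states_present]
        if np.ptp(np.concatenate(samples)) == 0:
            stat = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    stat = float(stats.kruskal(*samples).statistic)
                except ValueError:
                    stat = np.nan
        rows.append({"threshold": float(t), "accuracy": accuracy,
                     "statistic": stat, "risk_fraction": frac,
                     "feasible": frac >= min_risk_fraction})
    trace = pd.DataFrame(rows)
    feasible = trace[trace["feasible"]]
    if feasible.empty:
        raise ValueError(
            f"no grid threshold reaches overall risk fraction >= {min_risk_fraction}"
        )
    best_acc = feasible["accuracy"].max()
    tied = feasible[feasible["accuracy"] == best_acc]
    key = tied["statistic"].fillna(-np.inf)
    chosen = float(tied.loc[key == key.max(), "threshold"].max())
    return SlidingWindowResult(chosen, _make_calls(df, chosen, "sliding_window"), trace)


def threshold_sensitivity(indexes, cohort: Cohort, grid: np.ndarray) -> pd.DataFrame:
    """Per-state mean risk proportions and pairwise staging AUCs along a grid.

    One row per grid value with columns ``threshold``,
    ``mean_prop_<state>`` for each disease state present, and
    ``auc_<A>_vs_<B>`` for each ordered state pair (AUC of donor proportions
    separating the two states, higher-state group as positives). The output is
    sorted by threshold regardless of input grid order.
    """
    from .staging_assoc import roc_auc

    df = _as_index_table(indexes)
    grid = np.sort(np.asarray(grid, dtype=float))
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("grid must lie within [0, 1]")
    donor_of = df["cell_id"].map(cohort.cells["donor_id"])
    donors = pd.Index(sorted(donor_of.unique()))
    groups_of = cohort.donors["state"].reindex(donors).to_numpy()
    states_present = sorted(np.unique(groups_of))
    values = df["index"].to_numpy()

    rows = []
    for t in grid:
        props = _donor_proportions_at(values > t, donor_of.to_numpy(), donors).to_numpy()
        row = {"threshold": float(t)}
        for s in states_present:
            row[f"mean_prop_{STATE_LABELS[s]}"] = float(props[groups_of == s].mean())
        for hi in states_present:
            for lo in states_present:
                if hi <= lo:
                    continue
                mask = np.isin(groups_of, (lo, hi))
                labels = (groups_of[mask] == hi).astype(int)
                _, auc = roc_auc(props[mask], labels)
                row[f"auc_{STATE_LABELS[hi]}_vs_{STATE_LABELS[lo]}"] = auc
        rows.append(row)
    return pd.DataFrame(rows)
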