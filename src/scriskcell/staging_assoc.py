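"""Donor-level staging from risk-cell proportions, and clinical associations.

The single staging feature is each donor's risk-cell proportion for the
analyzed cell type. Donors are staged either by rule bands (< cut_low → ND,
[cut_low, cut_high] → preT2D, > cut_high → T2D; defaults 0.10 / 0.20) or by a
maximum-margin (SVM) classifier per state pair, evaluated leave-one-donor-out.
Performance is summarized by pairwise ROC/AUC with stratified-percentile
bootstrap confidence intervals; clinical covariates are related to the
proportion by Pearson correlation (pairwise-complete, two-sided t test) and
group differences by two-sided Wilcoxon rank-sum tests with
Benjamini–Hochberg correction across the three state pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .data_model import Cohort, CohortIntegrityError, STATE_LABELS

#: state pairs reported throughout, higher (more diseased) state first
STATE_PAIRS = ((2, 0), (2, 1), (1, 0))


def pair_name(hi: int, lo: int) -> str:
    return f"{STATE_LABELS[hi]}_vs_{STATE_LABELS[lo]}"


def donor_risk_proportions(risk: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Aggregate risk calls to one profile per donor.

    Returns a DataFrame indexed by donor_id with columns n_cells, n_risk,
    proportion, state, covering every donor owning at least one called cell.
    A call for a cell unknown to the cohort is an integrity error.
    """
    unknown = set(risk["cell_id"]) - set(cohort.cell_ids)
    if unknown:
        raise CohortIntegrityError(
            f"risk calls reference unknown cells: {sorted(unknown)[:10]}"
        )
    donor_of = risk["cell_id"].map(cohort.cells["donor_id"])
    grp = pd.DataFrame({"donor_id": donor_of.to_numpy(),
                        "is_risk": risk["is_risk"].to_numpy()}).groupby("donor_id")
    out = grp.agg(n_cells=("is_risk", "size"), n_risk=("is_risk", "sum"))
    out["proportion"] = out["n_risk"] / out["n_cells"]
    out["state"] = cohort.donors["state"].reindex(out.index)
    return out.sort_index()


def stage_by_rule(p: float, cut_low: float = 0.10, cut_high: float = 0.20) -> int:
    """Map one proportion to an ordinal state by the banding rule."""
    if not 0 <= cut_low < cut_high:
        raise ValueError(f"require 0 <= cut_low < cut_high, got {cut_low}, {cut_high}")
    if not 0 <= p <= 1:
        raise ValueError(f"proportion {p} outside [0, 1]")
    if p < cut_low:
        return 0
    if p <= cut_high:
        return 1
    return 2


def stage_by_rule_vec(p, cut_low: float = 0.10, cut_high: float = 0.20) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.asarray([stage_by_rule(v, cut_low, cut_high) for v in p])


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC step curve and AUC (Mann–Whitney concordance, ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)
    auc = float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, auc


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
                     seed: int = 0) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Resampling is within each class, so every replicate retains both classes.
    Deterministic for a given seed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("bootstrap_auc_ci requires both classes present")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n_pos, n_neg = len(pos), len(neg)
    for b in range(n_boot):
        p = pos[rng.integers(0, n_pos, n_pos)]
        n = neg[rng.integers(0, n_neg, n_neg)]
        ranks = stats.rankdata(np.concatenate([n, p]))
        reps[b] = (ranks[n_neg:].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class StagingResult:
    """Rule-based staging plus pairwise discrimination metrics."""

    predicted_state: pd.Series           # per-donor rule-based state
    accuracy: float                      # rule prediction vs true state
    pairwise: dict = field(default_factory=dict)  # pair name -> metrics dict
    cutoffs: tuple[float, float] = (0.10, 0.20)


def stage_donors(profiles: pd.DataFrame, cut_low: float = 0.10, cut_high: float = 0.20,
                 n_boot: int = 2000, level: float = 0.95, seed: int = 0) -> StagingResult:
    """Stage donors by the banding rule and score pairwise separability.

    For each state pair the raw proportion serves as the ROC score; the AUC
    gets a stratified bootstrap CI. Pairs with a state absent are skipped.
    """
    predicted = pd.Series(stage_by_rule_vec(profiles["proportion"], cut_low, cut_high),
                          index=profiles.index, name="predicted_state")
    accuracy = float((predicted == profiles["state"]).mean())
    pairwise = {}
    for hi, lo in STATE_PAIRS:
        mask = profiles["state"].isin([hi, lo])
        labels = (profiles.loc[mask, "state"] == hi).astype(int).to_numpy()
        if labels.sum() == 0 or (1 - labels).sum() == 0:
            continue
        scores = profiles.loc[mask, "proportion"].to_numpy()
        curve, auc = roc_auc(scores, labels)
        ci = bootstrap_auc_ci(scores, labels, n_boot=n_boot, level=level, seed=seed)
        pairwise[pair_name(hi, lo)] = {
            "auc": auc, "ci_lower": ci[0], "ci_upper": ci[1],
            "n_pos": int(labels.sum()), "n_neg": int(len(labels) - labels.sum()),
            "curve": curve,
        }
    return StagingResult(predicted, accuracy, pairwise, (cut_low, cut_high))


def fit_stage_classifier(profiles: pd.DataFrame, C: float = 1.0) -> dict:
    """Max-margin (linear SVM) staging on the single proportion feature.

    For each state pair, a linear SVC is evaluated leave-one-donor-out; the
    held-out decision values (normalized to margin distance, so scores are
    comparable across folds) are pooled into one ROC/AUC. The classifier
    refitted on all donors of the pair is returned alongside. Requires ≥2
    donors in each compared state.
    """
    out = {}
    for hi, lo in STATE_PAIRS:
        mask = profiles["state"].isin([hi, lo]).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"no donors for pair {pair_name(hi, lo)}")
        sub = profiles.loc[mask]
        y = (sub["state"] == hi).astype(int).to_numpy()
        if y.sum() < 2 or (1 - y).sum() < 2:
            raise ValueError(
                f"pair {pair_name(hi, lo)}: need >=2 donors per state "
                f"(have {int(y.sum())} {STATE_LABELS[hi]}, "
                f"{int(len(y) - y.sum())} {STATE_LABELS[lo]})"
            )
        X = sub[["proportion"]].to_numpy()
        scores = np.empty(len(sub))
        for i in range(len(sub)):          # LODO is order-independent by construction
            train = np.ones(len(sub), bool)
            train[i] = False
            if len(np.unique(y[train])) < 2:   # held-out donor was a whole class
                scores[i] = np.nan
                continue
            # standardize the single feature so the soft-margin scale is sane
            mu, sd = X[train].mean(), max(X[train].std(), 1e-12)
            clf = SVC(kernel="linear", C=C)
            clf.fit((X[train] - mu) / sd, y[train])
            w = float(np.abs(clf.coef_).sum()) or 1.0
            # margin distance in standardized units: comparable across folds
            scores[i] = float(clf.decision_function((X[[i]] - mu) / sd)[0]) / w
        ok = ~np.isnan(scores)
        _, auc = roc_auc(scores[ok], y[ok])
        mu, sd = X.mean(), max(X.std(), 1e-12)
        full = SVC(kernel="linear", C=C).fit((X - mu) / sd, y)
        out[pair_name(hi, lo)] = {
            "auc": auc,
            "scores": pd.Series(scores, index=sub.index, name="decision_score"),
            "labels": pd.Series(y, index=sub.index, name="label"),
            "classifier": {"coef": float(full.coef_[0, 0]),
                           "intercept": float(full.intercept_[0]),
                           "feature_mean": mu, "feature_sd": sd, "C": C},
        }
    return out


def pearson_assoc(x, y) -> tuple[float, float, int]:
    """Pearson r and two-sided p (t transform) on pairwise-complete data.

    Pairs with a missing value in either variable are dropped; the number of
    complete pairs used is returned. Requires ≥3 complete pairs and nonzero
    variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact for small tie-free groups, else
    tie- and continuity-corrected normal approximation."""
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def group_compare(profiles: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon rank-sum on proportions for all three state pairs, BH-adjusted.

    Returns a DataFrame with columns pair, W, p, p_adj (BH across the three
    pairs, input order preserved). Requires ≥2 donors per state in every
    compared pair.
    """
    rows = []
    for hi, lo in STATE_PAIRS:
        x = profiles.loc[profiles["state"] == hi, "proportion"].to_numpy()
        y = profiles.loc[profiles["state"] == lo, "proportion"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"pair {pair_name(hi, lo)}: need >=2 donors per state")
        w, p = _rank_sum_test(x, y)
        rows.append({"pair": pair_name(hi, lo), "W": w, "p": p,
                     "n_hi": len(x), "n_lo": len(y)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved.

    adj(i) = min over ranks j >= rank(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj
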