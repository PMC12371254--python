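"""Donor staging, ROC/AUC, bootstrap CIs, correlations, rank-sum tests, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from scriskcell.data_model import CohortIntegrityError
from scriskcell.staging_assoc import (bh_adjust, bootstrap_auc_ci,
                                      donor_risk_proportions,
                                      fit_stage_classifier, group_compare,
                                      pearson_assoc, roc_auc, stage_by_rule,
                                      stage_donors, _rank_sum_test)

from conftest import make_cohort


def profiles_from(props_by_state):
    rows = []
    for state, props in props_by_state.items():
        for i, p in enumerate(props):
            rows.append({"donor_id": f"s{state}d{i:02d}", "n_cells": 100,
                         "n_risk": int(round(p * 100)), "proportion": p,
                         "state": state})
    return pd.DataFrame(rows).set_index("donor_id")


class TestProportions:
    def test_arithmetic(self):
        cohort = make_cohort(np.ones((10, 2), int), ["d0"] * 10, states={"d0": 2})
        risk = pd.DataFrame({"cell_id": list(cohort.cell_ids),
                             "is_risk": [True, True] + [False] * 8})
        prof = donor_risk_proportions(risk, cohort)
        assert prof.loc["d0", "proportion"] == pytest.approx(0.2)
        assert prof.loc["d0", "n_cells"] == 10 and prof.loc["d0", "n_risk"] == 2

    def test_no_risk_cells(self):
        cohort = make_cohort(np.ones((6, 2), int), ["d0"] * 3 + ["d1"] * 3,
                             states={"d0": 0, "d1": 2})
        risk = pd.DataFrame({"cell_id": list(cohort.cell_ids), "is_risk": False})
        assert (donor_risk_proportions(risk, cohort)["proportion"] == 0).all()

    def test_unknown_cell_is_integrity_error(self):
        cohort = make_cohort(np.ones((2, 2), int), ["d0", "d0"])
        risk = pd.DataFrame({"cell_id": ["c000", "ghost"], "is_risk": True})
        with pytest.raises(CohortIntegrityError, match="ghost"):
            donor_risk_proportions(risk, cohort)

    def test_state_means_ordered_on_planted_cohort(self, default_run):
        res, _ = default_run
        means = res.profiles.groupby("state")["proportion"].mean()
        assert means[0] < means[1] < means[2]


class TestStageByRule:
    @pytest.mark.parametrize("p,expected", [
        (0.05, 0), (0.15, 1), (0.25, 2),     # band interiors
        (0.10, 1), (0.20, 1),                # closed band edges
        (0.0, 0), (1.0, 2),
    ])
    def test_banding(self, p, expected):
        assert stage_by_rule(p) == expected

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_partition_every_proportion_maps_once(self, p):
        assert stage_by_rule(p) in (0, 1, 2)

    def test_invalid_cutoffs(self):
        with pytest.raises(ValueError):
            stage_by_rule(0.5, cut_low=0.3, cut_high=0.2)


class TestRocAuc:
    def test_perfect_and_tied(self):
        assert roc_auc([1, 2, 3], [0, 0, 1])[1] == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1])[1] == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            scores = rng.choice(rng.random(max(2, n // 2)), n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert abs(auc - conc / (len(pos) * len(neg))) < 1e-12

    def test_negation_symmetry_without_ties(self):
        rng = np.random.default_rng(13)
        scores = rng.permutation(100).astype(float)
        labels = rng.integers(0, 2, 100)
        labels[0] = 1; labels[1] = 0
        assert roc_auc(scores, labels)[1] + roc_auc(-scores, labels)[1] == pytest.approx(1.0)

    def test_curve_is_monotone_step_from_origin_to_one(self):
        rng = np.random.default_rng(14)
        curve, _ = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert curve["fpr"].iloc[0] == 0 and curve["tpr"].iloc[0] == 0
        assert curve["fpr"].iloc[-1] == 1 and curve["tpr"].iloc[-1] == 1
        assert (curve["fpr"].diff().dropna() >= 0).all()
        assert (curve["tpr"].diff().dropna() >= 0).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestBootstrapCi:
    def test_perfect_separation_degenerate_interval(self):
        lo, hi = bootstrap_auc_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                                  n_boot=2000, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        scores, labels = rng.random(40), rng.integers(0, 2, 40)
        a = bootstrap_auc_ci(scores, labels, n_boot=500, seed=3)
        b = bootstrap_auc_ci(scores, labels, n_boot=500, seed=3)
        assert a == b

    def test_coverage_of_true_auc(self):
        # scores ~ N(0,1) / N(1,1): true AUC = Phi(1/sqrt(2))
        true_auc = stats.norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(16)
        hits = 0
        for i in range(200):
            neg = rng.normal(0, 1, 20)
            pos = rng.normal(1, 1, 20)
            scores = np.r_[neg, pos]
            labels = np.r_[np.zeros(20, int), np.ones(20, int)]
            lo, hi = bootstrap_auc_ci(scores, labels, n_boot=500, seed=i)
            hits += lo <= true_auc <= hi
        assert 0.88 <= hits / 200 <= 0.99


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        r, p, n = pearson_assoc(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_null_correlation_small(self):
        rng = np.random.default_rng(17)
        r, _, _ = pearson_assoc(rng.random(1000), rng.random(1000))
        assert abs(r) < 0.1

    def test_closed_form_t_oracle_on_fixed_table(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.7])
        r, p, n = pearson_assoc(x, y)
        rr = np.corrcoef(x, y)[0, 1]
        t = rr * np.sqrt((n - 2) / (1 - rr ** 2))
        p_expected = 2 * stats.t.sf(abs(t), n - 2)
        assert abs(r - rr) < 1e-12 and abs(p - p_expected) < 1e-10

    def test_pairwise_complete_drops_missing(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, np.nan, 3.0, 4.1, 5.2]
        _, _, n = pearson_assoc(x, y)
        assert n == 3

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pearson_assoc([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_assoc([1, 1, 1], [1, 2, 3])


def exact_rank_sum_p(x, y):
    """Two-sided exact Wilcoxon rank-sum p by full enumeration."""
    pooled = np.r_[x, y]
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        total += 1
    return count / total


class TestGroupCompare:
    def test_extreme_ranking_exact_p(self):
        w, p = _rank_sum_test(np.array([4.0, 5, 6]), np.array([1.0, 2, 3]))
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_rank_sum_p([4, 5, 6], [1, 2, 3]))

    def test_exact_matches_enumeration_on_random_small_groups(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            n1, n2 = rng.integers(3, 8, 2)
            pool = rng.permutation(100)[:n1 + n2].astype(float)  # tie-free pool
            x, y = pool[:n1], pool[n1:]
            _, p = _rank_sum_test(x, y)
            assert p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = _rank_sum_test(np.full(5, 0.3), np.full(6, 0.3))
        assert p == 1.0

    def test_three_pairs_with_bh(self):
        prof = profiles_from({0: [0.01, 0.02, 0.03, 0.04],
                              1: [0.11, 0.12, 0.13, 0.14],
                              2: [0.25, 0.27, 0.29, 0.31]})
        out = group_compare(prof)
        assert list(out["pair"]) == ["T2D_vs_ND", "T2D_vs_preT2D", "preT2D_vs_ND"]
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p"] < 0.05).all()

    def test_too_few_donors_raise(self):
        prof = profiles_from({0: [0.01], 1: [0.1, 0.2], 2: [0.3, 0.4]})
        with pytest.raises(ValueError):
            group_compare(prof)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_hand_stepped_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_reference(self):
        def brute(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(19)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 30)))
            assert np.array_equal(bh_adjust(p), brute(p))

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=20))
    def test_adjusted_never_below_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestStageClassifier:
    def test_perfectly_separated_auc_one(self):
        prof = profiles_from({0: [0.01, 0.02, 0.03], 1: [0.12, 0.14, 0.15],
                              2: [0.3, 0.35, 0.4]})
        out = fit_stage_classifier(prof)
        assert all(v["auc"] == 1.0 for v in out.values())

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(20)
        props = rng.random(60) * 0.4
        states = rng.permutation(np.repeat([0, 1, 2], 20))
        prof = profiles_from({s: props[states == s] for s in (0, 1, 2)})
        out = fit_stage_classifier(prof)
        assert 0.3 <= out["T2D_vs_ND"]["auc"] <= 0.7

    def test_missing_state_raises(self):
        prof = profiles_from({0: [0.01, 0.02], 2: [0.3, 0.4]})
        with pytest.raises(ValueError, match="preT2D"):
            fit_stage_classifier(prof)

    def test_lodo_scores_independent_of_donor_order(self):
        prof = profiles_from({0: [0.01, 0.05, 0.02], 1: [0.12, 0.18, 0.11],
                              2: [0.3, 0.22, 0.4]})
        shuffled = prof.sample(frac=1.0, random_state=0)
        a = fit_stage_classifier(prof)["T2D_vs_ND"]["scores"].sort_index()
        b = fit_stage_classifier(shuffled)["T2D_vs_ND"]["scores"].sort_index()
        pd.testing.assert_series_equal(a, b)


class TestStageDonors:
    def test_rule_staging_and_ci_bounds(self):
        prof = profiles_from({0: [0.02, 0.04, 0.06], 1: [0.12, 0.15, 0.18],
                              2: [0.25, 0.3, 0.35]})
        res = stage_donors(prof, n_boot=300, seed=0)
        assert res.accuracy == 1.0
        for pairw in res.pairwise.values():
            assert pairw["ci_lower"] <= pairw["auc"] <= pairw["ci_upper"]
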