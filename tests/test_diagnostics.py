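"""Statistical layer against independent oracles: pair-counting AUC,
exhaustive Youden search, full-enumeration Wilcoxon, closed-form trend."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lymphofoci.diagnostics import (DiagnosticThresholds, diagnose_lesion,
                                    exact_wilcoxon, fold_change, load_table4,
                                    malt_association_analysis, ordinal_trend,
                                    roc_auc, spearman, youden_cutoff)


def auc_pair_count(scores, labels):
    """Brute-force AUC: fraction of positive-negative pairs ordered
    correctly, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def wilcoxon_enumeration(a, b):
    """Exact two-sided p by explicit enumeration of every group assignment."""
    vals = np.concatenate([a, b])
    r = stats.rankdata(vals)
    n, n1 = len(vals), len(a)
    e = n1 * (n + 1) / 2.0
    d_obs = abs(r[:n1].sum() - e)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(r[list(idx)].sum() - e) >= d_obs - 1e-9:
            hits += 1
    return hits / total


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0

    def test_enumerated_small_examples(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc == 0.75

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.05

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = rng.choice([0, 1, 2, 5, 7.5, 10], size=n)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(auc_pair_count(scores, labels))
            assert r.ci_lo <= r.auc <= r.ci_hi

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestYoudenCutoff:
    def test_perfect_separation_gives_unit_youden(self):
        _, sens, spec, j = youden_cutoff([1, 2, 8, 9], [0, 0, 1, 1])
        assert (sens, spec, j) == (100.0, 100.0, 1.0)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = rng.choice(np.arange(0, 100, 2.5), size=20)
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                continue
            cutoff, sens, spec, j = youden_cutoff(scores, labels)
            # oracle: every distinct threshold (plus extremes), naive loops
            best_j = -np.inf
            cands = np.concatenate([np.unique(scores), [-np.inf, np.inf]])
            for t in cands:
                tp = sum(1 for s, l in zip(scores, labels) if l and s >= t)
                tn = sum(1 for s, l in zip(scores, labels) if not l and s < t)
                jj = tp / labels.sum() + tn / (len(labels) - labels.sum()) - 1
                best_j = max(best_j, jj)
            assert j == pytest.approx(best_j)
            # tie-break toward the lowest observed cutoff achieving best J
            achieving = []
            for t in np.unique(scores):
                tp = sum(1 for s, l in zip(scores, labels) if l and s >= t)
                tn = sum(1 for s, l in zip(scores, labels) if not l and s < t)
                jj = tp / labels.sum() + tn / (len(labels) - labels.sum()) - 1
                if jj == pytest.approx(best_j):
                    achieving.append(t)
            assert cutoff == min(achieving)


class TestExactWilcoxon:
    def test_small_example_enumerated_by_hand(self):
        # 6 equally likely assignments; 2 reach |S - E| >= observed
        assert exact_wilcoxon([1, 2], [3, 4]).p_two_sided == pytest.approx(1 / 3)

    def test_tied_singletons(self):
        assert exact_wilcoxon([5], [5]).p_two_sided == 1.0

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            n1 = int(rng.integers(1, n))
            vals = rng.choice([1.0, 2.0, 2.0, 3.5, 7.0], size=n)
            a, b = vals[:n1], vals[n1:]
            got = exact_wilcoxon(a, b)
            assert got.method == "exact"
            assert got.p_two_sided == pytest.approx(
                wilcoxon_enumeration(a, b), abs=1e-12)

    def test_all_split_sizes_of_one_tied_multiset(self):
        vals = np.array([1, 1, 2, 3, 3, 3, 4.5, 6, 6, 9], dtype=float)
        for n1 in range(1, len(vals)):
            a, b = vals[:n1], vals[n1:]
            assert exact_wilcoxon(a, b).p_two_sided == pytest.approx(
                wilcoxon_enumeration(a, b), abs=1e-12)

    def test_large_samples_fall_back_to_normal(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=25), rng.normal(1.0, size=25)
        got = exact_wilcoxon(a, b)
        assert got.method == "normal_approx"
        assert 0 < got.p_two_sided <= 1
        ref = stats.ranksums(a, b).pvalue
        assert got.p_two_sided == pytest.approx(ref, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            exact_wilcoxon([], [1.0])


class TestSpearmanAndTrend:
    def test_monotone_sequences(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 6, 8, 10])[0] == pytest.approx(1.0)
        assert spearman(x, [10, 8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_matches_rank_correlation_formula(self):
        rng = np.random.default_rng(6)
        x = rng.choice([1.0, 2.0, 2.0, 5.0, 8.0], size=12)
        y = rng.normal(size=12)
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_flat_groups_have_zero_slope(self):
        slope, _ = ordinal_trend([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert slope == pytest.approx(0.0)

    def test_decreasing_grades_detected(self):
        rng = np.random.default_rng(7)
        groups = [50 - 10 * g + rng.normal(0, 0.5, 12) for g in range(4)]
        slope, p = ordinal_trend(groups)
        assert slope < -9
        assert p < 1e-6

    def test_closed_form_normal_equations(self):
        groups = [[10.0, 12.0], [8.0, 9.0], [5.0, 4.0]]
        x = np.array([1, 1, 2, 2, 3, 3], dtype=float)
        y = np.array([10, 12, 8, 9, 5, 4], dtype=float)
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / ((x - x.mean()) ** 2).sum())
        slope, _ = ordinal_trend(groups)
        assert slope == pytest.approx(expected, abs=1e-12)


class TestMaltAssociation:
    def test_reference_table_loads(self):
        t = load_table4()
        assert len(t) == 19
        assert t["abnormal_pct"].max() == pytest.approx(67.7)

    def test_all_wild_table_degenerates_cleanly(self):
        t = load_table4().copy()
        t["t1118"] = "-"
        t["trisomy18q21"] = "-"
        rep = malt_association_analysis(t)
        assert rep.association.p_two_sided == 1.0
        assert rep.high_t1118_positive == 0
        assert rep.n_aberration_positive == 0

    def test_unknown_status_token_rejected(self):
        t = load_table4().copy()
        t.loc[0, "t1118"] = "??"
        with pytest.raises(ValueError, match="status token"):
            malt_association_analysis(t)

    def test_fold_change(self):
        assert fold_change(52.6, 21.9) == pytest.approx(2.4018, abs=1e-3)
        with pytest.raises(ZeroDivisionError):
            fold_change(1.0, 0.0)


class TestDiagnoseLesion:
    def test_follicular_branch(self):
        assert diagnose_lesion("follicular", 52.1).label == "FL-suspect"
        d = diagnose_lesion("follicular", 15.6)
        assert d.label.startswith("benign")
        assert any("27.2" in line for line in d.trace)

    def test_small_and_large_cell_branches(self):
        assert "suspect" in diagnose_lesion("small_cell", 44.5).label
        assert "benign" in diagnose_lesion("small_cell", 20.8).label
        assert "DLBCL" in diagnose_lesion("large_cell", 27.6).label

    def test_malt_routes_through_fish(self):
        class Fish:
            case_call = "translocation"
        assert "high-risk" in diagnose_lesion("malt", 40.0, fish=Fish()).label
        Fish.case_call = "wild"
        assert "low-risk" in diagnose_lesion("malt", 20.0, fish=Fish()).label
        with pytest.raises(ValueError):
            diagnose_lesion("malt", 40.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            diagnose_lesion("follicular", 120.0)
        with pytest.raises(ValueError):
            diagnose_lesion("unknown", 10.0)
        with pytest.raises(ValueError):
            DiagnosticThresholds(follicular_cutoff=0.0)
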