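"""Evaluation machinery: metrics, cutoffs, AUC, permutations, partograph."""

import numpy as np
import pandas as pd
import pytest

import mklabour as m
from mklabour.evaluation import _best_threshold, evaluate_score


class TestConfusionMetrics:
    def test_perfect_separation(self):
        rep = m.confusion_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert rep.se == 1.0 and rep.sp == 1.0 and rep.ppv == 1.0 and rep.npv == 1.0

    def test_threshold_below_all(self):
        rep = m.confusion_metrics([0.3, 0.7], [0, 1], 0.0)
        assert rep.se == 1.0 and rep.sp == 0.0

    def test_matches_brute_force_table(self):
        rng = np.random.default_rng(0)
        scores = rng.random(100)
        labels = rng.random(100) < 0.3
        th = 0.4
        rep = m.confusion_metrics(scores, labels, th)
        pred = scores >= th
        tp = np.sum(pred & labels); fn = np.sum(~pred & labels)
        tn = np.sum(~pred & ~labels); fp = np.sum(pred & ~labels)
        assert rep.se == pytest.approx(tp / (tp + fn))
        assert rep.sp == pytest.approx(tn / (tn + fp))
        assert rep.ppv == pytest.approx(tp / (tp + fp))
        assert rep.npv == pytest.approx(tn / (tn + fn))

    def test_single_class_flagged(self):
        rep = m.confusion_metrics([0.1, 0.9], [1, 1], 0.5)
        assert "single_class" in rep.flags
        assert np.isnan(rep.sp)


class TestLearnCutoff:
    def test_replicated_separable_pair(self):
        scores = np.tile([0.1, 0.9], 30)
        labels = np.tile([0, 1], 30)
        cut = m.learn_cutoff(scores, labels, n_folds=3, seed=0)
        assert cut.threshold == pytest.approx(0.5)
        assert all(c == 1.0 for c in cut.fold_min_se_sp)

    def test_all_equal_scores_cannot_separate(self):
        scores = np.full(60, 0.5)
        labels = np.tile([0, 1], 30)
        cut = m.learn_cutoff(scores, labels, n_folds=3, seed=0)
        assert all(c <= 0.5 for c in cut.fold_min_se_sp)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        labels = rng.random(300) < 0.3
        scores = labels * 1.0 + rng.normal(0, 0.8, 300)
        th, crit = _best_threshold(scores, labels)
        # exhaustive oracle over the same candidate set
        uniq = np.unique(scores)
        cands = (uniq[:-1] + uniq[1:]) / 2
        best, best_th = -1.0, None
        for c in cands:  # ties toward larger threshold
            rep = m.confusion_metrics(scores, labels, c)
            val = min(rep.se, rep.sp)
            if val >= best - 1e-15:
                if val > best or (best_th is not None and c > best_th):
                    best, best_th = max(best, val), c
        assert th == pytest.approx(best_th)
        assert crit == pytest.approx(best)

    def test_requires_both_classes(self):
        with pytest.raises(m.ValidationError):
            m.learn_cutoff([1.0, 2.0], [1, 1], n_folds=2)

    def test_threshold_semantics_consistency(self):
        """Applying the learned Th reproduces fold-level balance within bounds."""
        rng = np.random.default_rng(9)
        labels = rng.random(600) < 0.3
        scores = labels * 1.2 + rng.normal(0, 1, 600)
        cut = m.learn_cutoff(scores, labels, n_folds=3, seed=1)
        rep = m.confusion_metrics(scores, labels, cut.threshold)
        assert abs(rep.min_se_sp() - np.mean(cut.fold_min_se_sp)) < 0.15


class TestAUC:
    def test_perfect_and_ties(self):
        assert m.auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert m.auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_concordance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        pos, neg = scores[labels], scores[~labels]
        conc = np.mean(
            [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        )
        assert m.auc(scores, labels) == pytest.approx(conc)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.3
        assert m.auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        assert m.auc(np.exp(scores), labels) == pytest.approx(m.auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(m.ValidationError):
            m.auc([1.0, 2.0], [0, 0])


class TestPermutationPvalue:
    def test_separating_scores_small_p(self):
        labels = np.repeat([0, 1], 100)
        scores = labels + np.random.default_rng(0).normal(0, 0.05, 200)
        p = m.permutation_pvalue(scores, labels, n_perm=1000, seed=1)
        assert p <= 0.01

    def test_constant_scores_p_one(self):
        labels = np.tile([0, 1], 20)
        p = m.permutation_pvalue(np.zeros(40), labels, n_perm=50, seed=2)
        assert p == 1.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(7)
        scores, labels = rng.normal(size=60), rng.random(60) < 0.4
        a = m.permutation_pvalue(scores, labels, n_perm=300, seed=3)
        b = m.permutation_pvalue(scores, labels, n_perm=300, seed=3)
        assert a == b

    def test_null_mean_near_half(self):
        """Independent scores and labels give p-values centred near 0.5."""
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(200):
            scores = rng.normal(size=40)
            labels = np.zeros(40, dtype=bool)
            labels[:12] = True
            rng.shuffle(labels)
            ps.append(m.permutation_pvalue(scores, labels, n_perm=99, seed=rep))
        assert 0.4 <= np.mean(ps) <= 0.6


class TestPartograph:
    def test_on_line_is_negative(self):
        # 4 cm at t0, 10 cm six hours later: exactly 1 cm/h
        assert m.partograph_classify([0, 6], [4, 10], "alert") is False

    def test_fast_progress_negative(self):
        assert m.partograph_classify([0, 1, 2, 3], [4, 6, 8, 10], "alert") is False
        assert m.partograph_classify([0, 1, 2, 3], [4, 6, 8, 10], "action") is False

    def test_slow_progress_positive(self):
        # 1 cm over 5 h: 4 h behind the alert line -> alert positive, action on-line
        times, dil = [0, 5], [4, 5]
        assert m.partograph_classify(times, dil, "alert") is True
        assert m.partograph_classify(times, dil, "action") is False
        # a bit slower still -> strictly beyond the action line
        assert m.partograph_classify([0, 5.5], [4, 5], "action") is True

    def test_anchor_at_first_4cm_assessment(self):
        # line anchored at the first >= 4 cm assessment (5 cm at t = 2)
        times, dil = [0, 2, 4], [3, 5, 5.5]
        assert m.partograph_classify(times, dil, "alert") is True

    def test_never_reaches_threshold_not_evaluable(self):
        assert m.partograph_classify([0, 2], [2.0, 3.0], "alert") is None

    def test_cohort_scores_flag_low_dilatation(self, mid_pipeline):
        cohort, train_ids, *_ = mid_pipeline
        s = m.partograph_scores(cohort, train_ids, line="alert")
        dil_idx = cohort.feature_names.index("dilatation")
        mean, sd = cohort.encoder.moments["dilatation"]
        for sid, val in s.items():
            _, mat = cohort.state_matrix(sid)
            max_dil = (mat[:, dil_idx] * sd + mean).max()
            if np.isnan(val):
                assert max_dil < 4.0
            else:
                assert max_dil >= 4.0


class TestInterpretability:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(50, 3))
        corr = m.dimension_correlations(Y, pd.DataFrame({"v": Y[:, 0]}))
        assert corr.loc["dim1", "v"] == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(20, 2))
        v = rng.normal(size=20)
        corr = m.dimension_correlations(Y, pd.DataFrame({"v": v}))
        manual = np.mean((Y[:, 1] - Y[:, 1].mean()) * (v - v.mean())) / (
            Y[:, 1].std() * v.std()
        )
        assert corr.loc["dim2", "v"] == pytest.approx(manual)

    def test_independent_variable_small_rho(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            Y = rng.normal(size=(1000, 1))
            v = rng.normal(size=1000)
            rho = m.dimension_correlations(Y, pd.DataFrame({"v": v})).loc["dim1", "v"]
            hits += abs(rho) < 0.1
        assert hits >= 36  # >= 90% of repeats at n = 1000

    def test_zero_variance_flagged(self):
        Y = np.random.default_rng(3).normal(size=(10, 1))
        corr = m.dimension_correlations(Y, pd.DataFrame({"c": np.ones(10)}))
        assert np.isnan(corr.loc["dim1", "c"])
        assert "c" in corr.attrs["zero_variance"]


class TestOutcomeProfile:
    def test_uniform_rate_recovered(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 4000)
        y = rng.random(4000) < 0.2
        prof = m.outcome_rate_profile(x, y, n_bins=20)
        filled = prof[~prof["empty"]]
        se = np.sqrt(0.2 * 0.8 / filled["count"])
        assert np.all(np.abs(filled["rate"] - 0.2) < 3 * se + 1e-9)

    def test_densities_sum_to_one(self):
        rng = np.random.default_rng(5)
        prof = m.outcome_rate_profile(rng.normal(size=500), rng.random(500) < 0.5)
        assert prof["density"].sum() == pytest.approx(1.0)

    def test_monotone_gradient_recovered(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 6000)
        y = rng.random(6000) < x * 0.8
        prof = m.outcome_rate_profile(x, y, n_bins=10)
        rates = prof["rate"].to_numpy()
        # Spearman-like check: strongly increasing overall
        assert np.corrcoef(np.arange(10), rates)[0, 1] > 0.9

    def test_min_bins(self):
        with pytest.raises(m.ValidationError):
            m.outcome_rate_profile([1.0, 2.0], [0, 1], n_bins=1)


class TestSubgroups:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 600
        labels = rng.random(n) < 0.25
        scores = labels * 1.5 + rng.normal(0, 1, n)
        df = pd.DataFrame({"s": scores})
        return df, labels

    def test_trivial_partition_reproduces_global(self):
        df, labels = self._data()
        half = len(df) // 2
        part = m.subgroup_analysis(
            df.iloc[:half].reset_index(drop=True), labels[:half], np.zeros(half),
            df.iloc[half:].reset_index(drop=True), labels[half:], np.zeros(len(df) - half),
            score_names=["s"], n_folds=3, seed=0,
        )
        assert len(part.results) == 1
        res = part.results[0]
        cut = m.learn_cutoff(df["s"].iloc[:half], labels[:half], n_folds=3, seed=0)
        assert res.cutoffs["s"].threshold == pytest.approx(cut.threshold)
        rep = evaluate_score(df["s"].iloc[half:], labels[half:], cut.threshold)
        assert res.reports["s"].se == pytest.approx(rep.se)

    def test_engineered_subgroup_difference(self):
        rng = np.random.default_rng(1)
        n = 1000
        groups = (rng.random(n) < 0.5).astype(int)
        labels = rng.random(n) < 0.25
        # group 1 has strong coupling, group 0 almost none
        scores = labels * np.where(groups == 1, 2.5, 0.2) + rng.normal(0, 1, n)
        half = n // 2
        df = pd.DataFrame({"s": scores})
        part = m.subgroup_analysis(
            df.iloc[:half].reset_index(drop=True), labels[:half], groups[:half],
            df.iloc[half:].reset_index(drop=True), labels[half:], groups[half:],
            score_names=["s"], seed=1,
        )
        by_group = {r.group: r for r in part.results}
        assert (
            by_group[1].reports["s"].min_se_sp() > by_group[0].reports["s"].min_se_sp()
        )
        assert by_group[0].cutoffs["s"].threshold != by_group[1].cutoffs["s"].threshold

    def test_membership_counts_sum(self):
        df, labels = self._data(2)
        half = len(df) // 2
        groups = np.random.default_rng(3).integers(0, 3, len(df))
        part = m.subgroup_analysis(
            df.iloc[:half].reset_index(drop=True), labels[:half], groups[:half],
            df.iloc[half:].reset_index(drop=True), labels[half:], groups[half:],
            score_names=["s"], seed=0,
        )
        assert sum(r.n_train for r in part.results) == half
        assert sum(r.n_test for r in part.results) == len(df) - half

    def test_spatial_boxes_partition(self):
        rng = np.random.default_rng(4)
        Y_train = rng.normal(size=(300, 2))
        Y_test = rng.normal(size=(100, 2))
        g_train = m.assign_spatial_boxes(Y_train, Y_train, n1=3, n2=2)
        g_test = m.assign_spatial_boxes(Y_test, Y_train, n1=3, n2=2)
        assert set(g_train) <= set(range(6))
        assert set(g_test) <= set(range(6))
        # quantile boxes on the training set are near-balanced
        counts = np.bincount(g_train, minlength=6)
        assert counts.min() > 20
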