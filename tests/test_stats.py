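"""Statistical kernels against independent oracles.

Brute-force pair counting for the AUC, exhaustive enumeration for Youden
and Fisher, combinatorial enumeration for the exact Wilcoxon, hand-worked
product-limit and log-rank fixtures, scipy / lifelines / R pROC as
independent implementations, and permutation oracles for the DeLong test.
"""

import itertools
import math
import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from ctpet.stats import (
    DegenerateInputError,
    delong_paired_test,
    fisher_exact,
    km_estimate,
    logrank_test,
    roc_auc,
    sens_spec_at_cutoff,
    wilcoxon_rank_sum,
    youden_cutoff,
)


def brute_auc(scores, labels):
    """P(score+ > score-) + 0.5 P(tie) by explicit pair counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    total = wins = ties = 0
    for p in pos:
        for q in neg:
            total += 1
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / total


def swap_permutation_p(a, b, labels, reps, seed):
    """Permutation p for equal paired AUCs: swap markers within subjects."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    obs = brute_auc(a, labels) - brute_auc(b, labels)
    r = np.random.default_rng(seed)
    count = 0
    n = len(labels)
    for _ in range(reps):
        sw = r.random(n) < 0.5
        aa = np.where(sw, b, a)
        bb = np.where(sw, a, b)
        if abs(brute_auc(aa, labels) - brute_auc(bb, labels)) >= abs(obs) - 1e-12:
            count += 1
    return count / reps


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.3] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_three_of_four_concordant_pairs(self):
        assert roc_auc([0.9, 0.3, 0.7, 0.1], [1, 1, 0, 0]).auc == 0.75

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_pair_counting(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 40))
        scores = np.round(r.normal(size=n), 1)  # rounding forces ties
        labels = r.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_auc(scores, labels), abs=1e-12
        )

    def test_negating_scores_flips_auc_exactly(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(12, int), np.zeros(18, int)]
        assert roc_auc(-scores, labels).auc == 1 - roc_auc(scores, labels).auc

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=25)
        labels = np.r_[np.ones(10, int), np.zeros(15, int)]
        curve = roc_auc(scores, labels).curve
        assert tuple(curve[0, :2]) == (0.0, 0.0)
        assert tuple(curve[-1, :2]) == (1.0, 1.0)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)

    def test_ci_brackets_auc_and_shrinks_with_n(self, rng):
        labels_small = np.r_[np.ones(20, int), np.zeros(20, int)]
        labels_big = np.r_[np.ones(200, int), np.zeros(200, int)]
        small = roc_auc(rng.normal(labels_small, 1.0), labels_small)
        big = roc_auc(rng.normal(labels_big, 1.0), labels_big)
        for roc in (small, big):
            assert roc.ci_low <= roc.auc <= roc.ci_high
            assert roc.variance >= 0
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# DeLong paired test
# ---------------------------------------------------------------------------


class TestDelong:
    def test_identical_markers_give_z_zero_p_one(self, paired_scores_n12):
        a, _, labels = paired_scores_n12
        res = delong_paired_test(a, a, labels)
        assert res.z == 0.0 and res.pvalue == 1.0

    def test_swapping_markers_negates_z_keeps_p(self, paired_scores_n12):
        a, b, labels = paired_scores_n12
        fwd = delong_paired_test(a, b, labels)
        rev = delong_paired_test(b, a, labels)
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)
        assert fwd.pvalue == pytest.approx(rev.pvalue, abs=1e-12)

    def test_agrees_with_r_proc_reference(self, paired_scores_n12, tmp_path):
        """Same placement-value covariance formula as pROC's delong.test."""
        a, b, labels = paired_scores_n12
        script = tmp_path / "delong.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"a <- c({', '.join(map(repr, a.tolist()))})\n"
            f"b <- c({', '.join(map(repr, b.tolist()))})\n"
            f"y <- c({', '.join(map(str, labels.tolist()))})\n"
            "r <- roc.test(roc(y, a, quiet=TRUE), roc(y, b, quiet=TRUE),"
            " method='delong')\n"
            "cat(sprintf('%.12f %.12f', r$statistic, r$p.value))\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300, check=True,
        )
        z_ref, p_ref = map(float, out.stdout.split())
        res = delong_paired_test(a, b, labels)
        assert res.z == pytest.approx(z_ref, abs=1e-9)
        assert res.pvalue == pytest.approx(p_ref, abs=1e-9)

    def test_converges_to_permutation_p_at_moderate_n(self):
        """The asymptotic p approaches the exact swap-permutation p."""
        n = 120
        r = np.random.default_rng(1)
        labels = np.r_[np.ones(60, int), np.zeros(60, int)]
        latent = r.normal(labels * 0.8, 1.0)
        a = latent + r.normal(0, 0.7, n)
        b = latent + r.normal(0, 0.9, n)
        p_perm = swap_permutation_p(a, b, labels, reps=2000, seed=7)
        res = delong_paired_test(a, b, labels)
        assert res.pvalue == pytest.approx(p_perm, abs=0.04)

    def test_zero_variance_flagged_not_p_zero(self):
        labels = [1, 1, 0, 0]
        res = delong_paired_test([4, 3, 2, 1], [1, 2, 3, 4], labels)
        # both AUCs degenerate (1 and 0) with zero placement variance
        assert not res.evaluable
        assert math.isnan(res.pvalue)


# ---------------------------------------------------------------------------
# Youden cutoff and confusion metrics
# ---------------------------------------------------------------------------


class TestYouden:
    def test_perfect_separation_midpoint_cutoff(self):
        res = youden_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.youden_j == pytest.approx(1.0)
        assert 0.2 < res.cutoff < 0.8
        assert res.cutoff == pytest.approx(0.5)  # midpoint of 0.2 and 0.8

    def test_all_equal_scores_give_j_zero(self):
        res = youden_cutoff([1.0] * 6, [1, 1, 1, 0, 0, 0])
        assert res.youden_j == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        scores = np.round(r.normal(size=20), 1)
        labels = np.r_[np.ones(8, int), np.zeros(12, int)]
        r.shuffle(labels)
        if labels.sum() in (0, 20):
            labels[0], labels[-1] = 0, 1
        best_j = -1.0
        grid = np.r_[scores - 1e-6, scores + 1e-6, scores.min() - 1]
        for c in grid:
            sens, spec = sens_spec_at_cutoff(scores, labels, c)
            best_j = max(best_j, sens + spec - 1)
        res = youden_cutoff(scores, labels)
        assert res.youden_j == pytest.approx(best_j, abs=1e-9)

    def test_ties_break_toward_higher_specificity(self):
        # two cutoffs attain J = 0.5; the higher-specificity one must win
        scores = [4, 3, 2, 1]
        labels = [1, 0, 1, 0]
        res = youden_cutoff(scores, labels)
        sens, spec = sens_spec_at_cutoff(scores, labels, res.cutoff)
        assert spec == 1.0  # cutoff above 3 rejects both negatives


class TestSensSpec:
    def test_perfect_classifier(self):
        assert sens_spec_at_cutoff([3, 4, 1, 2], [1, 1, 0, 0], 2.5) == (1, 1)

    def test_cutoff_below_everything(self):
        sens, spec = sens_spec_at_cutoff([3, 4, 1, 2], [1, 1, 0, 0], 0.0)
        assert (sens, spec) == (1.0, 0.0)

    def test_matches_direct_confusion_count(self, rng):
        scores = rng.normal(size=10)
        labels = np.r_[np.ones(4, int), np.zeros(6, int)]
        cutoff = float(np.median(scores))
        sens, spec = sens_spec_at_cutoff(scores, labels, cutoff)
        tp = sum(s >= cutoff for s, l in zip(scores, labels) if l)
        tn = sum(s < cutoff for s, l in zip(scores, labels) if not l)
        assert sens == tp / 4 and spec == tn / 6


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


class TestFisher:
    def test_diagonal_two_by_two(self):
        # margins (2,2)/(2,2): three tables with probs 1/6, 4/6, 1/6
        p, odds = fisher_exact([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-12)
        assert math.isinf(odds)

    def test_symmetric_null_table(self):
        p, odds = fisher_exact([[1, 1], [1, 1]])
        assert p == 1.0 and odds == 1.0

    @pytest.mark.parametrize("table", [
        [[0, 0], [3, 5]], [[2, 4], [0, 0]], [[0, 3], [0, 5]],
    ])
    def test_zero_margin_gives_p_one(self, table):
        assert fisher_exact(table)[0] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_probability_ordering(self, seed):
        r = np.random.default_rng(seed)
        table = r.integers(0, 12, (2, 2))
        p, _ = fisher_exact(table)
        p_ref = sps.fisher_exact(table).pvalue
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 1], [2, 3]])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_exact_small_sample_worked_value(self):
        # only the 2 most extreme of C(6,3)=20 splits: p = 2/20
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 5], [2, 1, 5, 2])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_full_enumeration(self, seed):
        r = np.random.default_rng(seed)
        x = np.round(r.normal(size=5), 1)
        y = np.round(r.normal(size=6), 1)
        w, p = wilcoxon_rank_sum(x, y)
        ranks = sps.rankdata(np.r_[x, y])
        mean_w = 5 * 12 / 2
        dev = abs(ranks[:5].sum() - mean_w)
        count = sum(
            abs(ranks[list(idx)].sum() - mean_w) >= dev - 1e-9
            for idx in itertools.combinations(range(11), 5)
        )
        assert p == pytest.approx(count / math.comb(11, 5), abs=1e-12)

    def test_normal_approximation_close_to_scipy(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.4, 1, 50)
        _, p = wilcoxon_rank_sum(x, y)
        p_ref = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(p_ref, rel=0.02)

    def test_power_against_one_sd_shift(self):
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, 200)
            y = r.normal(1, 1, 200)
            _, p = wilcoxon_rank_sum(x, y)
            rejections += p < 0.01
        assert rejections == 20

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        # events at 1 and 3, censoring at 2: S(1)=2/3, S(3)=2/3 * 0 = 0
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.evaluate(1) == pytest.approx(2 / 3)
        assert curve.evaluate(2.5) == pytest.approx(2 / 3)
        assert curve.evaluate(3) == 0.0

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.evaluate(99) == 1.0

    def test_no_censoring_equals_ecdf_complement(self, rng):
        times = rng.exponential(10, 50)
        curve = km_estimate(times, np.ones(50, int))
        for t in curve.event_times:
            assert curve.evaluate(t) == pytest.approx(
                (times > t).mean(), abs=1e-12
            )

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(12, 80)
        events = rng.integers(0, 2, 80)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


class TestLogrank:
    def test_hand_worked_two_group_fixture(self):
        # groups A: (1,e),(3,e); B: (2,e),(4,c)
        # per-event 2x2 tables give O-E = 2 - 4/3, V = 13/18, chi2 = 8/13
        times = [1, 3, 2, 4]
        events = [1, 1, 1, 0]
        group = [0, 0, 1, 1]
        res = logrank_test(times, events, group)
        assert res.chi2 == pytest.approx(8 / 13, abs=1e-12)
        assert res.pvalue == pytest.approx(float(sps.chi2.sf(8 / 13, 1)))

    def test_identical_groups_give_chi2_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 0, 1, 1, 0, 1]
        group = [0, 0, 0, 1, 1, 1]
        res = logrank_test(times, events, group)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        n = 60
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        group = rng.integers(0, 2, n)
        events[0] = 1
        group[:2] = [0, 1]
        res = logrank_test(times, events, group)
        ref = ll_logrank(
            times[group == 0], times[group == 1],
            events[group == 0], events[group == 1],
        )
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.pvalue == pytest.approx(ref.p_value, rel=1e-9)

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            times = r.exponential(10, 80)
            events = (times < 30).astype(int)
            times = np.minimum(times, 30)
            group = r.integers(0, 2, 80)
            if group.sum() in (0, 80):
                continue
            ps.append(logrank_test(times, events, group).pvalue)
        ks = sps.kstest(ps, "uniform").pvalue
        assert ks > 0.01

    def test_power_under_hazard_ratio_three(self):
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            t0 = r.exponential(30, 300)
            t1 = r.exponential(10, 300)
            times = np.r_[t0, t1]
            events = (times < 36).astype(int)
            times = np.minimum(times, 36)
            group = np.r_[np.zeros(300, int), np.ones(300, int)]
            rejections += logrank_test(times, events, group).pvalue < 0.01
        assert rejections >= 19

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            logrank_test([1, 2], [1, 1], [1, 1])

    def test_no_events_flagged_non_evaluable(self):
        res = logrank_test([1, 2], [0, 0], [0, 1])
        assert not res.evaluable
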