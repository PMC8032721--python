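"""Hypothesis tests, effect sizes, resampling and rater-agreement kappas,
each checked against an independent route (enumeration, scipy,
scikit-learn or statsmodels)."""

import numpy as np
import pytest
from scipy import stats

from lesionmgmt.agreement import (
    cohens_d,
    cohens_kappa,
    fleiss_kappa,
    loo_cohen_protocol,
    majority_vote,
    mcnemar_mid_p,
    pairwise_cohen_summary,
    panel_model_fleiss,
    resample_summary,
    wilcoxon_signed_rank,
)
from lesionmgmt.cohort import RaterPanel, simulate_rater_panel


class TestWilcoxon:
    def test_exact_enumeration_small_samples(self):
        # all-positive differences (1, 2, 3): W+ = 6, p = 2/8
        res = wilcoxon_signed_rank(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.p_value == pytest.approx(0.25)
        # differences (1, 2, -3): W+ = W- = 3, every pattern as extreme
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, -3.0]), np.zeros(3))
        assert res.p_value == pytest.approx(1.0)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(4), np.ones(4))

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            ours = wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(x, y, alternative="two-sided", mode="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_scipy_normal_approximation_large_n(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60) + 0.3
        ours = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, alternative="two-sided", mode="approx", correction=False)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])) == 0.0

    def test_hand_computed_pooled_sd(self):
        x = np.array([1.0, 1.0, 3.0, 3.0])
        y = np.array([0.0, 0.0, 2.0, 2.0])
        assert cohens_d(x, y) == pytest.approx(0.8660, abs=1e-4)
        assert cohens_d(y, x) == pytest.approx(-cohens_d(x, y))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            cohens_d(np.ones(3), np.ones(3))


class TestResampleSummary:
    def test_constant_vector_collapses(self):
        s = resample_summary(np.full(10, 3.5), seed=0)
        assert (s.mean, s.ci_low, s.ci_high) == (3.5, 3.5, 3.5)

    def test_grand_mean_near_sample_mean(self, rng):
        values = rng.normal(size=200)
        s = resample_summary(values, seed=1)
        se = values.std(ddof=1) / np.sqrt(s.sample_size)
        assert abs(s.mean - values.mean()) < 3 * se

    def test_deterministic_and_validates_sample_size(self, rng):
        values = rng.normal(size=50)
        a = resample_summary(values, seed=7)
        b = resample_summary(values, seed=7)
        assert a == b
        with pytest.raises(ValueError):
            resample_summary(values, sample_size=60, replace=False, seed=0)

    def test_bootstrap_mode_uses_replacement(self, rng):
        values = rng.normal(size=30)
        s = resample_summary(values, sample_size=30, replace=True, seed=3)
        assert s.replace and s.sample_size == 30


class TestMcNemarMidP:
    def test_reference_values(self):
        assert mcnemar_mid_p(5, 5).p_value == pytest.approx(1.0)
        assert mcnemar_mid_p(0, 10).p_value == pytest.approx(0.000977, abs=1e-6)
        assert mcnemar_mid_p(0, 0).p_value == 1.0
        with pytest.raises(ValueError):
            mcnemar_mid_p(-1, 2)

    def test_mid_p_sandwiched_by_binomial_enumeration(self, rng):
        """2 P(X < k) <= mid-p <= 2 P(X <= k) with X ~ Binomial(n, 1/2),
        computed by direct enumeration of the binomial pmf."""
        for _ in range(30):
            n01, n10 = rng.integers(0, 25, size=2)
            n = n01 + n10
            if n == 0:
                continue
            k = min(n01, n10)
            pmf = np.array([stats.binom.pmf(i, n, 0.5) for i in range(n + 1)])
            below, at_or_below = pmf[:k].sum(), pmf[: k + 1].sum()
            mid = mcnemar_mid_p(n01, n10).p_value
            assert 2 * below - 1e-9 <= mid <= min(1.0, 2 * at_or_below) + 1e-9
            assert mid == pytest.approx(
                min(1.0, 2 * (at_or_below - 0.5 * pmf[k])), abs=1e-12
            )


class TestCohensKappa:
    def test_reference_cases(self):
        assert cohens_kappa(np.array([1, 0, 1]), np.array([1, 0, 1])) == 1.0
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        assert cohens_kappa(a, b) == pytest.approx(0.0)
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            a = rng.integers(0, 2, size=30)
            b = rng.integers(0, 2, size=30)
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                continue
            assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-10)


class TestFleissKappa:
    def test_unanimous_panel(self):
        panel = RaterPanel(np.tile([1, 0, 1], (4, 1)), list("abcd"), list("xyz"))
        assert fleiss_kappa(panel) == pytest.approx(1.0)

    def test_hand_computed_two_item_panel(self):
        # items with votes (1,1,0) and (0,0,0) among 3 raters
        panel = RaterPanel(np.array([[1, 0], [1, 0], [0, 0]]), list("abc"), list("xy"))
        assert fleiss_kappa(panel) == pytest.approx(0.25)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        votes = rng.integers(0, 2, size=(12, 40))
        panel = RaterPanel(votes, [f"r{i}" for i in range(12)], [f"c{j}" for j in range(40)])
        table, _ = aggregate_raters(votes.T)
        assert fleiss_kappa(panel) == pytest.approx(sm_fleiss(table), abs=1e-10)

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(RaterPanel(np.array([[1, 0]]), ["a"], ["x", "y"]))


class TestMajorityAndProtocols:
    def test_majority_vote_and_tie_rules(self):
        panel = RaterPanel(np.array([[1, 1], [1, 0], [0, 0]]), list("abc"), list("xy"))
        np.testing.assert_array_equal(majority_vote(panel), [1, 0])
        tied = RaterPanel(np.array([[1, 0], [0, 1]]), list("ab"), list("xy"))
        np.testing.assert_array_equal(majority_vote(tied), [1, 1])  # EXC default
        np.testing.assert_array_equal(majority_vote(tied, tie_rule="noexc"), [0, 0])

    def test_loo_cohen_unanimous_and_chance(self):
        unanimous = RaterPanel(
            np.tile([1, 0, 1, 0], (5, 1)), [f"r{i}" for i in range(5)], list("wxyz")
        )
        mean, sd, excluded = loo_cohen_protocol(unanimous)
        assert (mean, sd, excluded) == (1.0, 0.0, 0)
        truth = np.r_[np.ones(50), np.zeros(50)].astype(int)
        chance = simulate_rater_panel(truth, 60, sensitivity=0.6, specificity=0.4, seed=2)
        mean, sd, _ = loo_cohen_protocol(chance)
        assert abs(mean) < 3 * sd / np.sqrt(chance.n_raters) + 0.05

    def test_panel_model_fleiss_modes(self):
        votes = np.tile([1, 0, 1, 0, 1], (7, 1))
        panel = RaterPanel(votes, [f"r{i}" for i in range(7)], [f"c{j}" for j in range(5)])
        model = votes[0]
        mean, sd = panel_model_fleiss(panel, model, subset_size=None)
        assert (mean, sd) == (1.0, 0.0)
        a = panel_model_fleiss(panel, model, subset_size=3, n_reps=50, seed=4)
        b = panel_model_fleiss(panel, model, subset_size=3, n_reps=50, seed=4)
        assert a == b
        with pytest.raises(ValueError):
            panel_model_fleiss(panel, model, subset_size=7)

    def test_exchangeable_model_scores_like_a_rater(self):
        """A model that is just one more simulated rater should score a
        leave-one-out Fleiss kappa compatible with the panel's own."""
        truth = np.r_[np.ones(20), np.zeros(80)].astype(int)
        panel_all = simulate_rater_panel(truth, 21, 0.8, 0.8, seed=8)
        model = panel_all.recommendations[0]
        rest = RaterPanel(
            panel_all.recommendations[1:],
            panel_all.rater_ids[1:],
            panel_all.case_ids,
        )
        mean_model, _ = panel_model_fleiss(rest, model, subset_size=None)
        base = fleiss_kappa(rest)
        pair_mean, pair_sd = pairwise_cohen_summary(rest)
        assert abs(mean_model - base) < 2 * pair_sd
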