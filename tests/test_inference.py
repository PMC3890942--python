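import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from percross import (
    exclude_player_rerun,
    f_test_equal_variance,
    gated_comparison,
    one_tailed_two_sample_t,
    synchrony_analysis,
)
from percross.inference import annotate_click_categories, summarize_clicks


class TestFTest:
    def test_identical_samples_give_f_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        f, p, equal = f_test_equal_variance(x, x)
        assert f == 1.0 and p == 1.0 and equal

    def test_known_variance_ratio(self):
        rng = np.random.default_rng(0)
        x = 2.0 * rng.standard_normal(10)
        y = rng.standard_normal(10)
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        f, p, _ = f_test_equal_variance(x, y)
        assert f == pytest.approx(max(vx, vy) / min(vx, vy))
        # closed-form two-sided p from the F(9, 9) distribution
        assert p == pytest.approx(2 * sps.f.sf(f, 9, 9))

    def test_one_constant_sample_rejects_equality(self):
        f, p, equal = f_test_equal_variance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isinf(f) and p == 0.0 and not equal

    def test_both_constant_is_degenerate(self):
        with pytest.raises(ValueError):
            f_test_equal_variance([1.0, 1.0], [2.0, 2.0])


class TestOneTailedT:
    def test_equal_samples_give_half(self):
        x = [1.0, 2.0, 3.0]
        t, df, p = one_tailed_two_sample_t(x, x, equal_var=True, direction="greater")
        assert t == 0.0 and p == 0.5

    def test_pooled_textbook_instance(self):
        # x={1,2,3}, y={2,3,4}: pooled s^2 = 1, t = -1/sqrt(2/3), df = 4
        t, df, p = one_tailed_two_sample_t(
            [1, 2, 3], [2, 3, 4], equal_var=True, direction="less"
        )
        assert t == pytest.approx(-1 / np.sqrt(2 / 3))
        assert df == 4
        assert p == pytest.approx(sps.t.cdf(t, 4))
        # independent oracle: scipy's pooled test halved for one tail
        ref = sps.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue / 2)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 2.0, size=12)
        y = rng.normal(0.0, 0.5, size=20)
        t, df, p = one_tailed_two_sample_t(x, y, equal_var=False, direction="greater")
        ref = sps.ttest_ind(x, y, equal_var=False, alternative="greater")
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_welch_equals_student_for_balanced_equal_variance(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 3.0, 4.0, 5.0]
        t1, df1, p1 = one_tailed_two_sample_t(x, y, equal_var=True, direction="greater")
        t2, df2, p2 = one_tailed_two_sample_t(x, y, equal_var=False, direction="greater")
        assert t1 == pytest.approx(t2)
        assert df1 == pytest.approx(df2)

    def test_direction_must_be_explicit(self):
        with pytest.raises(ValueError):
            one_tailed_two_sample_t([1, 2], [3, 4], equal_var=True, direction="auto")


class TestGatedComparison:
    def test_equal_variances_choose_student(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 1.0, size=30)
        y = rng.normal(0.0, 1.0, size=30)
        res = gated_comparison(x, y, direction="greater")
        assert res.chosen_test == "student"
        assert res.df == 58

    def test_large_variance_ratio_chooses_welch(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 4.0, size=30)
        y = rng.normal(0.0, 1.0, size=30)
        res = gated_comparison(x, y, direction="greater")
        assert res.chosen_test == "welch"
        assert res.df < 58

    def test_p_decreases_with_sample_size_on_average(self):
        rng = np.random.default_rng(4)
        p_small, p_large = [], []
        for _ in range(40):
            for n, sink in ((10, p_small), (80, p_large)):
                x = rng.normal(0.4, 1.0, size=n)
                y = rng.normal(0.0, 1.0, size=n)
                sink.append(gated_comparison(x, y, direction="greater").p_one_tailed)
        assert np.mean(p_large) < np.mean(p_small)

    def test_type_i_error_near_nominal_alpha(self):
        # two equal-mean normal groups; the gated one-tailed test should
        # reject at close to the nominal 5% rate
        rng = np.random.default_rng(5)
        reps = 10_000
        rejections = 0
        for _ in range(reps):
            x = rng.standard_normal(15)
            y = rng.standard_normal(15)
            if gated_comparison(x, y, direction="greater").p_one_tailed < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.04 < rate < 0.06  # ~3 Monte-Carlo sigma around 0.05


class TestSynchrony:
    def test_simultaneous_clicks_have_zero_pairwise_delay(self):
        pairs = [(10.0, 10.0), (20.0, 20.0), (30.0, 30.0)]
        pairwise, randomized = synchrony_analysis(pairs)
        assert (pairwise.delays == 0).all()
        assert pairwise.frequencies.sum() == pytest.approx(1.0)
        assert randomized.frequencies.sum() == pytest.approx(1.0)

    def test_cross_pairings_enumerated_exhaustively(self):
        # alternating click times 10 s and 20 s: the cross-trial delays are
        # computable by hand over all i != j pairings
        pairs = [(10.0, 10.0), (20.0, 20.0)]
        _, randomized = synchrony_analysis(pairs)
        assert sorted(randomized.delays.tolist()) == [10.0, 10.0]
        pairs = [(10.0, 10.0), (20.0, 20.0), (10.0, 10.0)]
        _, randomized = synchrony_analysis(pairs)
        # 3*2 ordered cross pairs: t1 x t2 off-diagonal
        assert sorted(randomized.delays.tolist()) == [0.0, 0.0, 10.0, 10.0, 10.0, 10.0]

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            synchrony_analysis([(10.0, 11.0)])

    def test_randomized_invariant_to_trial_order(self):
        rng = np.random.default_rng(6)
        pairs = [(float(a), float(a) + float(d)) for a, d in
                 zip(rng.uniform(5, 55, 12), rng.uniform(0, 3, 12))]
        _, r1 = synchrony_analysis(pairs)
        _, r2 = synchrony_analysis(pairs[::-1])
        assert sorted(r1.delays.tolist()) == pytest.approx(sorted(r2.delays.tolist()))


def _toy_clicks():
    rows = [
        # team 0: two joint-success trials
        dict(team=0, trial=0, player=0, target="avatar", tt=0.8, pas=4),
        dict(team=0, trial=0, player=1, target="avatar", tt=0.7, pas=4),
        dict(team=0, trial=1, player=0, target="avatar", tt=0.6, pas=4),
        dict(team=0, trial=1, player=1, target="avatar", tt=0.5, pas=3),
        # team 1: single success and wrong clicks, with the sole PAS-1 reporter
        dict(team=1, trial=0, player=0, target="avatar", tt=0.2, pas=1),
        dict(team=1, trial=0, player=1, target="shadow", tt=0.1, pas=2),
        dict(team=1, trial=1, player=0, target="avatar", tt=0.3, pas=1),
    ]
    return pd.DataFrame(rows)


class TestExcludePlayerRerun:
    def test_unknown_player_rejected(self):
        with pytest.raises(ValueError, match="players present"):
            exclude_player_rerun(_toy_clicks(), team=9, player=0)

    def test_excluding_sole_low_pas_reporter_shifts_means(self):
        res = exclude_player_rerun(_toy_clicks(), team=1, player=0)
        # the excluded player's PAS-1 reports vanish, raising the mean of
        # the categories they occupied
        full = res["full"]["mean_pas"]
        excl = res["excluded"]["mean_pas"]
        assert full["single_success"] == pytest.approx(1.0)
        assert excl["single_success"] is None  # no single-success clicks remain
        assert res["full"]["n_clicks"] == 7
        assert res["excluded"]["n_clicks"] == 5

    def test_categories_recomputed_after_exclusion(self):
        clicks = _toy_clicks()
        # removing player 1 of team 0 turns the joint successes into singles
        res = exclude_player_rerun(clicks, team=0, player=1)
        assert res["excluded"]["category_counts"]["joint_success"] == 0
        assert res["excluded"]["category_counts"]["single_success"] == 4

    def test_annotation_matches_trial_classification(self):
        annotated = annotate_click_categories(_toy_clicks())
        assert list(annotated["category"]) == [
            "joint_success", "joint_success", "joint_success", "joint_success",
            "single_success", "wrong", "single_success",
        ]
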