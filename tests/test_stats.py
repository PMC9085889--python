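import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mcmflow.stats import (
    behavior_summary,
    cluster_permutation,
    divergence,
    holm,
    posthoc,
    rm_anova_gtc,
    spearman,
    tetris_score,
)


def anova_oracle(diffs, groups):
    """Textbook sums-of-squares decomposition of the two-way mixed design
    (between factor group, within factor condition), written as explicit
    loops independent of the implementation."""
    subjects, n_cond = diffs.shape
    grand = diffs.mean()
    levels = list(dict.fromkeys(groups))
    ss_total = sum((diffs[i, j] - grand) ** 2 for i in range(subjects) for j in range(n_cond))
    ss_bs = sum(n_cond * (diffs[i].mean() - grand) ** 2 for i in range(subjects))
    ss_g = sum(
        n_cond * sum(groups == g) * (diffs[groups == g].mean() - grand) ** 2 for g in levels
    )
    ss_c = sum(subjects * (diffs[:, j].mean() - grand) ** 2 for j in range(n_cond))
    ss_cells = sum(
        sum(groups == g) * (diffs[groups == g][:, j].mean() - grand) ** 2
        for g in levels
        for j in range(n_cond)
    )
    ss_gc = ss_cells - ss_g - ss_c
    ss_subj = ss_bs - ss_g
    ss_err = ss_total - ss_bs - ss_c - ss_gc
    df_subj, df_err = subjects - 2, (subjects - 2) * (n_cond - 1)
    return {
        "group_x_time": (ss_g / 1) / (ss_subj / df_subj),
        "time_x_condition": (ss_c / (n_cond - 1)) / (ss_err / df_err),
        "group_x_time_x_condition": (ss_gc / (n_cond - 1)) / (ss_err / df_err),
    }


class TestRmAnova:
    def test_all_identical_values_give_zero_f(self):
        values = np.full((10, 2, 3), 3.7)
        groups = np.array(["training"] * 5 + ["control"] * 5)
        res = rm_anova_gtc(values, groups)
        assert res["group_x_time_x_condition"].F == 0.0

    def test_matches_sums_of_squares_oracle(self, rng):
        values = rng.standard_normal((21 + 20, 2, 3))
        groups = np.array(["training"] * 21 + ["control"] * 20)
        values[:21, 1, 0] += 0.8  # planted interaction in training-group rest
        res = rm_anova_gtc(values, groups)
        oracle = anova_oracle(values[:, 1, :] - values[:, 0, :], groups)
        for name, f_expected in oracle.items():
            assert res[name].F == pytest.approx(f_expected, abs=1e-8)

    def test_matches_pingouin_mixed_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        values = rng.standard_normal((12, 2, 3))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        diffs = values[:, 1, :] - values[:, 0, :]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "group": np.repeat(groups, 3),
                "condition": np.tile(["rest", "easy", "hard"], 12),
                "value": diffs.ravel(),
            }
        )
        pg = pingouin.mixed_anova(
            df, dv="value", within="condition", between="group", subject="subject"
        ).set_index("Source")
        res = rm_anova_gtc(values, groups)
        assert res["group_x_time"].F == pytest.approx(pg.loc["group", "F"], rel=1e-6)
        assert res["time_x_condition"].F == pytest.approx(pg.loc["condition", "F"], rel=1e-6)
        assert res["group_x_time_x_condition"].F == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6
        )

    def test_null_p_values_uniform(self, rng):
        groups = np.array(["t"] * 10 + ["c"] * 10)
        pvals = [
            rm_anova_gtc(rng.standard_normal((20, 2, 3)), groups)[
                "group_x_time_x_condition"
            ].p
            for _ in range(2000)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_cells_rejected(self):
        values = np.ones((6, 2, 3))
        values[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_gtc(values, np.array(["a"] * 3 + ["b"] * 3))


class TestPosthoc:
    def test_paired_t_equals_one_sample_t_on_differences(self, rng):
        values = rng.standard_normal((8, 2, 3))
        groups = np.array(["t"] * 4 + ["c"] * 4)
        res = posthoc(values, groups, condition=1)
        d = values[:4, 1, 1] - values[:4, 0, 1]
        t_ref = sps.ttest_1samp(d, 0.0)
        assert res["within_group"]["t"]["t"] == pytest.approx(t_ref.statistic)
        assert res["within_group"]["t"]["p"] == pytest.approx(t_ref.pvalue)

    def test_interaction_f_is_squared_two_sample_t(self, rng):
        values = rng.standard_normal((12, 2, 3))
        groups = np.array(["t"] * 6 + ["c"] * 6)
        res = posthoc(values, groups, 0)
        d = values[:, 1, 0] - values[:, 0, 0]
        t = sps.ttest_ind(d[:6], d[6:]).statistic
        assert res["interaction"].F == pytest.approx(t**2)

    def test_equal_distributions_give_uniform_p(self, rng):
        groups = np.array(["t"] * 8 + ["c"] * 8)
        pvals = [
            posthoc(rng.standard_normal((16, 2, 3)), groups, 0)["interaction"].p
            for _ in range(1000)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_shift_guarded(self):
        values = np.zeros((6, 2, 3))
        values[:3, 1, :] = 1.0  # exact +1 shift in group 't'
        res = posthoc(values, np.array(["t"] * 3 + ["c"] * 3), 0)
        assert res["within_group"]["t"]["t"] == np.inf
        assert res["within_group"]["t"]["p"] == 0.0


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm([0.03]) == pytest.approx([0.03])

    def test_step_down_example(self):
        np.testing.assert_allclose(holm([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(holm([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_step_down_definition(self, rng):
        p = rng.random(9)
        order = np.argsort(p)
        expected = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(p) - rank) * p[idx])
            expected[idx] = min(running, 1.0)
        np.testing.assert_allclose(holm(p), expected, atol=1e-12)

    def test_adjusted_at_least_raw_and_smallest_is_bonferroni(self, rng):
        p = rng.random(7)
        adj = holm(p)
        assert np.all(adj >= p - 1e-15)
        assert adj[np.argmin(p)] == pytest.approx(min(1.0, p.min() * len(p)))


class TestClusterPermutation:
    def test_identity_permutation_reproduces_observed_statistic(self, rng):
        maps = rng.standard_normal((12, 6, 6, 3))
        groups = np.array(["t"] * 6 + ["c"] * 6)
        res = cluster_permutation(maps, groups, n_perm=100, seed=0)
        t_direct = sps.ttest_ind(maps[:6], maps[6:], axis=0).statistic
        np.testing.assert_allclose(res.t_map, t_direct, atol=1e-10)

    def test_huge_planted_cluster_detected(self, rng):
        detected = 0
        groups = np.array(["t"] * 8 + ["c"] * 8)
        for seed in range(20):
            r = np.random.default_rng(seed)
            maps = r.standard_normal((16, 8, 8, 4))
            maps[:8, 1:7, 1:7, 1:3] += 3.0
            res = cluster_permutation(maps, groups, n_perm=100, seed=seed)
            if res.labels.max() > 0:
                detected += 1
        assert detected >= 19

    def test_familywise_error_near_nominal_on_null(self):
        groups = np.array(["t"] * 6 + ["c"] * 6)
        false_pos = 0
        n_runs = 300
        for seed in range(n_runs):
            r = np.random.default_rng(10_000 + seed)
            maps = r.standard_normal((12, 7, 7, 3))
            res = cluster_permutation(
                maps, groups, n_perm=100, cluster_forming_p=0.01, seed=seed
            )
            if res.labels.max() > 0:
                false_pos += 1
        rate = false_pos / n_runs
        assert 0.01 <= rate <= 0.10  # nominal 0.05 within Monte-Carlo slack

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="permutations"):
            cluster_permutation(
                rng.standard_normal((6, 4, 4, 2)), np.array(["t"] * 3 + ["c"] * 3),
                n_perm=100,
            )


class TestDivergence:
    def test_equal_rest_and_task_give_zero(self):
        assert divergence(2.0, 2.0) == 0.0

    def test_worked_value(self):
        assert divergence(3.0, 1.0) == pytest.approx(1.0)

    def test_invariant_to_common_positive_scaling(self, rng):
        rest, hard = rng.random(10) + 0.5, rng.random(10) + 0.5
        np.testing.assert_allclose(
            divergence(rest, hard), divergence(5.0 * rest, 5.0 * hard)
        )

    def test_zero_mean_is_error(self):
        with pytest.raises(ValueError):
            divergence(1.0, -1.0)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        rho, _ = spearman(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))


class TestBehavior:
    def test_tetris_line_constants_and_speed_scaling(self):
        assert tetris_score(1, 0) == 40
        assert tetris_score(2, 0) == 100
        assert tetris_score(3, 0) == 300
        assert tetris_score(4, 0) == 1200
        assert tetris_score(4, 3) == 4800
        with pytest.raises(ValueError):
            tetris_score(5, 0)
        with pytest.raises(ValueError):
            tetris_score(1, -1)

    def test_flat_learning_curve_auc_equals_level(self):
        days = np.arange(1, 11)
        table = pd.DataFrame(
            {
                "subject": 0,
                "group": "training",
                "kind": ["scan"] * 4 + ["training"] * len(days),
                "time": ["M1", "M2", "M1", "M2"] + list(days),
                "condition": ["easy", "easy", "hard", "hard"] + ["hard"] * len(days),
                "score_per_min": [1, 2, 1, 2] + [7.0] * len(days),
            }
        )
        out = behavior_summary(table)
        assert out["auc_norm"][0] == pytest.approx(7.0)

    def test_doubling_scores_gives_fold_two(self):
        rows = []
        for s in range(5):
            m1 = 10 + s
            rows.append((s, "training", "scan", "M1", "hard", m1))
            rows.append((s, "training", "scan", "M2", "hard", 2 * m1))
        table = pd.DataFrame(
            rows, columns=["subject", "group", "kind", "time", "condition", "score_per_min"]
        )
        fc = behavior_summary(table)["fold_changes"]["training"]["hard"]
        assert fc["ratio_of_means"] == pytest.approx(2.0)
        assert fc["mean_of_ratios"] == pytest.approx(2.0)
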