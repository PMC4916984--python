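import numpy as np
import pytest
from scipy import stats

from promoterlearn import (
    PredictionSubmission,
    chi_square_distance,
    error_profile,
    evaluate_submission,
    pearson_score,
    permutation_pvalue,
    rank_distance,
    spearman_score,
)
from promoterlearn.dream_evaluation import combined_scores


def make_pool(rng, ids, n_teams, lo=0.5, hi=2.0):
    return [
        PredictionSubmission(f"team{j}", dict(zip(ids, rng.uniform(lo, hi, len(ids)))))
        for j in range(n_teams)
    ]


class TestStatistics:
    def test_pearson_identity_and_reversal(self, rng):
        obs = rng.uniform(0.5, 2.0, 20)
        assert pearson_score(obs, obs) == pytest.approx(1.0)
        assert pearson_score(-obs, obs) == pytest.approx(-1.0)

    def test_pearson_hand_computation(self):
        # textbook formula on pred=[1,2,3], obs=[6,4,5]: r = -1/2
        assert pearson_score([1, 2, 3], [6, 4, 5]) == pytest.approx(-0.5)

    def test_pearson_constant_vector_errors(self):
        with pytest.raises(ValueError):
            pearson_score([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_monotone_transform_is_one(self, rng):
        obs = rng.uniform(0.5, 2.0, 15)
        assert spearman_score(np.exp(obs), obs) == pytest.approx(1.0)
        assert spearman_score(-obs, obs) == pytest.approx(-1.0)

    def test_spearman_with_ties_matches_manual_average_ranks(self):
        pred = [1.0, 2.0, 2.0, 3.0, 4.0]
        obs = [10.0, 20.0, 30.0, 40.0, 50.0]
        # average ranks of pred: [1, 2.5, 2.5, 4, 5]
        manual = stats.pearsonr([1, 2.5, 2.5, 4, 5], [1, 2, 3, 4, 5]).statistic
        assert spearman_score(pred, obs) == pytest.approx(float(manual))

    def test_chi2_zero_iff_equal_and_simple_case(self):
        assert chi_square_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert chi_square_distance([2.0], [1.0]) == pytest.approx(1.0)
        assert chi_square_distance([2.0], [1.0], denom="uniform") == pytest.approx(1.0)

    def test_chi2_residual_scaling_is_quadratic(self, rng):
        obs = rng.uniform(0.5, 2.0, 30)
        resid = rng.normal(0, 0.3, 30)
        base = chi_square_distance(obs + resid, obs)
        scaled = chi_square_distance(obs + 2.5 * resid, obs)
        assert scaled == pytest.approx(2.5**2 * base)

    def test_chi2_requires_positive_observed(self):
        with pytest.raises(ValueError):
            chi_square_distance([1.0], [0.0])

    def test_rank_distance_identity_and_reversal_closed_form(self, rng):
        obs = np.sort(rng.uniform(0.5, 2.0, 25))
        assert rank_distance(obs, obs) == 0.0
        n = len(obs)
        assert rank_distance(obs[::-1], obs) == pytest.approx((n**2 - 1) / 3)

    def test_rank_distance_monotone_invariance(self, rng):
        pred = rng.uniform(0.5, 2.0, 20)
        obs = rng.uniform(0.5, 2.0, 20)
        base = rank_distance(pred, obs)
        assert rank_distance(np.log(pred), np.exp(obs)) == pytest.approx(base)

    def test_rank_distance_sum_variant(self, rng):
        pred = rng.uniform(0.5, 2.0, 10)
        obs = rng.uniform(0.5, 2.0, 10)
        assert rank_distance(pred, obs, variant="sum") == pytest.approx(
            10 * rank_distance(pred, obs)
        )


class TestPermutationPvalue:
    def test_perfect_submission_small_p(self, rng):
        ids = [f"p{i}" for i in range(30)]
        obs = rng.uniform(0.5, 2.0, 30)
        mine = PredictionSubmission("me", dict(zip(ids, obs)))
        pool = make_pool(rng, ids, 10)
        p = permutation_pvalue(mine, pool, obs, "pearson", n_perm=1000, seed=0,
                               promoter_ids=ids)
        assert p <= 0.01

    def test_single_worse_replicate_gives_half(self, rng):
        ids = [f"p{i}" for i in range(10)]
        obs = rng.uniform(0.5, 2.0, 10)
        mine = PredictionSubmission("me", dict(zip(ids, obs)))
        pool = make_pool(rng, ids, 5)
        p = permutation_pvalue(mine, pool, obs, "chi2", n_perm=1, seed=0,
                               promoter_ids=ids)
        assert p == pytest.approx(0.5)  # add-one formula: (1+0)/(1+1)

    def test_pvalues_never_zero(self, rng):
        ids = [f"p{i}" for i in range(20)]
        obs = rng.uniform(0.5, 2.0, 20)
        mine = PredictionSubmission("me", dict(zip(ids, obs)))
        pool = make_pool(rng, ids, 8)
        for stat in ("pearson", "spearman", "chi2", "rank"):
            p = permutation_pvalue(mine, pool, obs, stat, n_perm=200, seed=1,
                                   promoter_ids=ids)
            assert 0 < p <= 1

    def test_empty_pool_errors(self, rng):
        ids = ["p0", "p1", "p2"]
        mine = PredictionSubmission("me", dict(zip(ids, [1.0, 2.0, 3.0])))
        with pytest.raises(ValueError):
            permutation_pvalue(mine, [mine], [1.0, 2.0, 3.0], "pearson",
                               n_perm=10, seed=0, promoter_ids=ids)

    @pytest.mark.parametrize("statistic", ["pearson", "rank"])
    def test_null_submission_p_uniform(self, statistic):
        """A submission drawn by the null scheme itself has ~uniform p-values."""
        rng = np.random.default_rng(77)
        ids = [f"p{i}" for i in range(40)]
        obs = rng.uniform(0.5, 2.0, 40)
        pool = make_pool(rng, ids, 12)
        pool_values = np.stack([s.vector(ids) for s in pool])
        pvals = []
        for rep in range(100):
            idx = rng.integers(0, len(pool), size=40)
            mine = PredictionSubmission(
                "me", dict(zip(ids, pool_values[idx, np.arange(40)]))
            )
            pvals.append(
                permutation_pvalue(mine, pool, obs, statistic, n_perm=499,
                                   seed=rep, promoter_ids=ids)
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestEvaluateSubmission:
    def test_combined_score_arithmetic(self):
        product, score = combined_scores([0.1, 0.1, 0.1, 0.1])
        assert product == pytest.approx(1e-4)
        assert score == pytest.approx(1.0)

    def test_perfect_submission_statistics(self, rng):
        ids = [f"p{i}" for i in range(25)]
        obs = dict(zip(ids, rng.uniform(0.5, 2.0, 25)))
        mine = PredictionSubmission("me", dict(obs))
        pool = make_pool(rng, ids, 6)
        report = evaluate_submission(mine, pool, obs, n_perm=200, seed=0,
                                     promoter_ids=ids)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.spearman_rho == pytest.approx(1.0)
        assert report.chi2_distance == 0.0
        assert report.rank_distance == 0.0

    def test_report_internally_consistent(self, rng):
        ids = [f"p{i}" for i in range(20)]
        obs = dict(zip(ids, rng.uniform(0.5, 2.0, 20)))
        mine = PredictionSubmission(
            "me", {i: v + rng.normal(0, 0.2) for i, v in obs.items()}
        )
        pool = make_pool(rng, ids, 7)
        report = evaluate_submission(mine, pool, obs, n_perm=300, seed=3,
                                     promoter_ids=ids)
        ps = [report.p_pearson, report.p_spearman, report.p_chi2, report.p_rank]
        product, score = combined_scores(ps)
        assert report.overall_product == pytest.approx(product)
        assert report.overall_score == pytest.approx(score)
        assert all(0 < p <= 1 for p in ps)

    def test_misaligned_ids_error(self, rng):
        ids = ["p0", "p1", "p2"]
        obs = {"p0": 1.0, "p1": 2.0, "p2": 3.0}
        mine = PredictionSubmission("me", {"p0": 1.0, "p1": 2.0})  # p2 missing
        pool = make_pool(rng, ids, 3)
        with pytest.raises(ValueError, match="p2"):
            evaluate_submission(mine, pool, obs, n_perm=10, seed=0, promoter_ids=ids)


class TestErrorProfile:
    def test_perfect_predictions(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        out = error_profile(obs, obs, ["natural"] * 4)
        assert np.array_equal(out.abs_error, np.zeros(4))
        assert out.error_activity_r is None  # undefined: constant errors

    def test_group_shift_detected(self, rng):
        n = 40
        labels = ["natural"] * n + ["mutated"] * n
        obs = np.concatenate([rng.uniform(1, 2, n), rng.uniform(1, 2, n)])
        errors = np.concatenate([rng.normal(0.1, 0.02, n), rng.normal(0.5, 0.02, n)])
        pred = obs + errors
        out = error_profile(pred, obs, labels)
        assert out.group_mean_error["mutated"] > out.group_mean_error["natural"]
        assert out.group_p_value < 1e-6

    def test_error_vector_invariant_to_relabeling(self, rng):
        obs = rng.uniform(1, 2, 10)
        pred = obs + rng.normal(0, 0.1, 10)
        a = error_profile(pred, obs, ["x"] * 10)
        b = error_profile(pred, obs, ["y"] * 5 + ["z"] * 5)
        assert np.array_equal(a.abs_error, b.abs_error)

    def test_small_group_skips_test_with_warning(self, rng, caplog):
        obs = rng.uniform(1, 2, 5)
        pred = obs + rng.normal(0, 0.1, 5)
        with caplog.at_level("WARNING"):
            out = error_profile(pred, obs, ["a"] * 4 + ["b"])
        assert out.group_p_value is None
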