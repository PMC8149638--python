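"""Monte-Carlo proximity test, empirical p-values and cohort statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from plaqueprox import (
    NullDistribution,
    PointSet,
    ProximityResult,
    build_roi,
    count_correlation,
    empirical_p,
    null_distribution,
    observed_statistic,
    per_sample_cohort_test,
    pooled_first_k_test,
    randomize_markers,
)
from plaqueprox.randomization import spearman_rho

from oracles import bfs_geodesic, paired_t, pooled_t, spearman_brute


def _result(distances, sample_id="s"):
    d = np.asarray(distances, float)
    fin = np.isfinite(d)
    return ProximityResult(
        sample_id=sample_id,
        distances=d,
        mean_distance=float(d[fin].mean()),
        n_markers=int(fin.sum()),
        n_unreachable=int((~fin).sum()),
    )


def _null(replicate_stats, replicate_distances=None, sample_id="s"):
    stats_ = np.asarray(replicate_stats, float)
    rep = (
        np.asarray(replicate_distances, float)
        if replicate_distances is not None
        else np.zeros((0, 1))
    )
    return NullDistribution(
        sample_id=sample_id,
        B=stats_.size,
        replicate_stats=stats_,
        replicate_distances=rep,
        rng_seed=None,
        n_markers=rep.shape[1] if rep.size else 1,
    )


class TestObservedStatistic:
    def test_markers_on_references_give_zero_mean(self, open_roi):
        refs = PointSet([[3, 3], [6, 6]], "reference")
        marks = PointSet([[3, 3], [6, 6], [3, 3]], "marker")
        assert observed_statistic(open_roi, refs, marks).mean_distance == 0

    def test_chebyshev_mean_on_open_grid(self):
        roi = build_roi(np.ones((10, 10), bool))
        res = observed_statistic(
            roi, PointSet([[0, 0]], "reference"), PointSet([[0, 1], [0, 3]], "marker")
        )
        assert res.mean_distance == 2.0

    def test_clustered_sample_matches_bfs_oracle(self, rng):
        from plaqueprox import SyntheticConfig, make_roi, place_markers, place_references

        cfg = SyntheticConfig(grid_shape=(96, 96), n_references=10, n_markers=60, sigma=5.0)
        roi = make_roi(cfg, rng, sample_id="ad-like")
        refs = place_references(roi, 10, rng)
        marks = place_markers(roi, refs, cfg, rng)
        res = observed_statistic(roi, refs, marks)
        oracle = bfs_geodesic(roi.grid, refs.points)
        expected = oracle[marks.points[:, 0], marks.points[:, 1]]
        assert res.mean_distance == pytest.approx(expected[np.isfinite(expected)].mean())


class TestRandomizeMarkers:
    def test_count_and_containment(self, rng):
        mask = np.zeros((20, 20), bool)
        mask[3:15, 5:12] = True
        roi = build_roi(mask)
        ps = randomize_markers(roi, 100, rng)
        assert len(ps) == 100
        assert mask[ps.points[:, 0], ps.points[:, 1]].all()

    def test_single_pixel_roi_forced(self, rng):
        mask = np.zeros((4, 4), bool)
        mask[2, 1] = True
        ps = randomize_markers(build_roi(mask), 5, rng)
        assert (ps.points == [2, 1]).all()

    def test_two_pixel_roi_frequencies_binomial(self):
        mask = np.zeros((1, 2), bool)
        mask[:] = True
        ps = randomize_markers(build_roi(mask), 10_000, np.random.default_rng(7))
        n_left = int((ps.points[:, 1] == 0).sum())
        sd = np.sqrt(10_000 * 0.25)
        assert abs(n_left - 5_000) <= 3 * sd

    def test_zero_draws_rejected(self, open_roi, rng):
        with pytest.raises(ValueError):
            randomize_markers(open_roi, 0, rng)

    def test_reproducible_given_seed(self, open_roi):
        a = randomize_markers(open_roi, 50, np.random.default_rng(3))
        b = randomize_markers(open_roi, 50, np.random.default_rng(3))
        assert np.array_equal(a.points, b.points)


class TestNullDistribution:
    def test_saturated_references_give_zero_stats(self):
        roi = build_roi(np.ones((5, 5), bool))
        rr, cc = np.nonzero(roi.grid)
        refs = PointSet(np.column_stack([rr, cc]), "reference")
        null = null_distribution(roi, refs, n_markers=7, B=25, seed=0)
        assert np.all(null.replicate_stats == 0)

    def test_replicate_count_is_B(self, open_roi, single_reference):
        null = null_distribution(open_roi, single_reference, n_markers=5, B=500, seed=0)
        assert null.replicate_stats.shape == (500,)
        assert null.B == 500

    def test_mean_converges_to_roi_average_of_field(self):
        # exact expectation of a replicate mean = ROI-wide mean of the field
        from plaqueprox import geodesic_distance_transform

        rng = np.random.default_rng(11)
        mask = np.ones((16, 16), bool)
        mask[4:7, 4:9] = False
        roi = build_roi(mask)
        refs = PointSet([[0, 0], [15, 15]], "reference")
        field = geodesic_distance_transform(roi, refs)
        exact = field.values[mask].mean()
        sd = field.values[mask].std()
        B, n = 200, 10
        null = null_distribution(roi, refs, n_markers=n, B=B, seed=int(rng.integers(2**31)))
        se = sd / np.sqrt(B * n)
        assert abs(null.null_mean - exact) <= 3 * se

    def test_determinism_bit_identical(self, open_roi, single_reference):
        a = null_distribution(open_roi, single_reference, 20, B=100, seed=42)
        b = null_distribution(open_roi, single_reference, 20, B=100, seed=42)
        assert np.array_equal(a.replicate_stats, b.replicate_stats)
        assert np.array_equal(a.replicate_distances, b.replicate_distances)

    def test_first_k_retention(self, open_roi, single_reference):
        null = null_distribution(open_roi, single_reference, 8, B=30, seed=1, first_k=10)
        assert null.replicate_distances.shape == (10, 8)
        # retained rows reproduce the corresponding replicate means
        assert np.allclose(null.replicate_distances.mean(axis=1), null.replicate_stats[:10])


class TestEmpiricalP:
    def test_observed_below_all_replicates(self):
        p = empirical_p(_result([0.0]), _null(np.linspace(1, 2, 500)))
        assert p == pytest.approx(1 / 501)

    def test_observed_above_all_replicates(self):
        p = empirical_p(_result([9.0]), _null(np.linspace(1, 2, 500)))
        assert p == 1.0

    def test_tie_counts_as_less_equal(self):
        assert empirical_p(_result([1.0]), _null([1.0])) == 1.0

    def test_super_uniform_under_exchangeability(self):
        # CSR markers and null replicates are exchangeable, so
        # P(p <= a) <= a on the attainable grid {1/(B+1), ..., 1}
        rng = np.random.default_rng(5)
        roi = build_roi(np.ones((32, 32), bool))
        refs = PointSet([[5, 5], [20, 25]], "reference")
        B, n_data = 39, 300
        pvals = []
        for i in range(n_data):
            marks = randomize_markers(roi, 15, rng)
            obs = observed_statistic(roi, refs, marks)
            null = null_distribution(roi, refs, 15, B=B, seed=int(rng.integers(2**31)))
            pvals.append(empirical_p(obs, null))
        pvals = np.asarray(pvals)
        for alpha in (1 / (B + 1), 5 / (B + 1), 0.5, 1.0):
            frac = (pvals <= alpha).mean()
            # binomial slack at 3 sigma
            assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_data) + 1e-12


class TestPooledFirstK:
    def test_group_sizes_match_study_design(self, rng):
        roi = build_roi(np.ones((64, 64), bool), sample_id="fig2d")
        refs = PointSet(rng.integers(0, 64, (16, 2)), "reference", "fig2d")
        marks = PointSet(rng.integers(0, 64, (28, 2)), "marker", "fig2d")
        obs = observed_statistic(roi, refs, marks)
        null = null_distribution(roi, refs, 28, B=20, seed=0, first_k=10)
        res = pooled_first_k_test(obs, null, k=10)
        assert (res.n_observed, res.n_random) == (28, 280)

    def test_identical_groups_give_t0_p1(self):
        obs = _result([2.0, 2.0, 2.0])
        null = _null([2.0], replicate_distances=[[2.0, 2.0, 2.0]])
        res = pooled_first_k_test(obs, null, k=1)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_hand_computed_pooled_t(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        res = pooled_first_k_test(_result(a), _null([np.mean(b)], [b]), k=1)
        t_exp, p_exp = pooled_t(a, b)
        assert res.statistic == pytest.approx(t_exp)
        assert res.p_value == pytest.approx(p_exp)

    def test_welch_flag_changes_statistic(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 30.0, 4.0, 50.0, 6.0, 7.0]
        pooled = pooled_first_k_test(_result(a), _null([np.mean(b)], [b]), k=1)
        welch = pooled_first_k_test(_result(a), _null([np.mean(b)], [b]), k=1, welch=True)
        assert pooled.p_value != welch.p_value

    def test_k_beyond_retained_rejected(self):
        null = _null(np.ones(20), replicate_distances=np.ones((5, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            pooled_first_k_test(_result([1.0, 2.0]), null, k=10)


class TestCohortTest:
    def test_five_samples_give_five_rows(self):
        results = [
            (_result([i + 1.0, i + 2.0], f"s{i}"), _null(np.full(10, i + 5.0), sample_id=f"s{i}"))
            for i in range(5)
        ]
        summary = per_sample_cohort_test(results)
        assert len(summary.per_sample) == 5
        assert list(summary.per_sample["sample_id"]) == [f"s{i}" for i in range(5)]

    def test_degenerate_equal_pairs_report_p1(self):
        results = [
            (_result([2.0], f"s{i}"), _null([2.0], sample_id=f"s{i}")) for i in range(3)
        ]
        summary = per_sample_cohort_test(results)
        assert summary.paired_statistic == 0.0 and summary.paired_p == 1.0

    def test_matches_hand_computed_paired_t(self):
        obs_means = [1.0, 2.0, 3.0]
        null_means = [2.0, 4.0, 3.0]
        results = [
            (_result([m], f"s{i}"), _null([nm], sample_id=f"s{i}"))
            for i, (m, nm) in enumerate(zip(obs_means, null_means))
        ]
        summary = per_sample_cohort_test(results)
        t_exp, p_exp = paired_t(obs_means, null_means)
        assert summary.paired_statistic == pytest.approx(t_exp)
        assert summary.paired_p == pytest.approx(p_exp)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            per_sample_cohort_test([(_result([1.0]), _null([1.0]))])


class TestCountCorrelation:
    def test_monotone_increasing_gives_rho_one(self):
        rho, p = count_correlation([(10, 1), (20, 2), (30, 3), (40, 4), (50, 5)])
        assert rho == pytest.approx(1.0)
        # exact permutation: only the two strictly monotone pairings reach |rho|=1
        assert p == pytest.approx(2 / 120)

    def test_monotone_decreasing_gives_rho_minus_one(self):
        rho, _ = count_correlation([(50, 1), (40, 2), (30, 3), (20, 4), (10, 5)])
        assert rho == pytest.approx(-1.0)

    def test_tied_pairs_match_brute_force_ranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        rho, _ = count_correlation(list(zip(x, y)))
        assert rho == pytest.approx(spearman_brute(x, y))
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic)  # library cross-check

    def test_constant_vector_reported_undefined(self):
        rho, p = count_correlation([(5, 1), (5, 2), (5, 3)])
        assert np.isnan(rho) and np.isnan(p)

    def test_large_n_t_approximation_close_to_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = count_correlation(list(zip(x, y)))
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            count_correlation([(1, 2), (3, 4)])

    def test_spearman_rho_helper_matches_scipy(self, rng):
        x = rng.integers(0, 5, 12).astype(float)
        y = rng.integers(0, 5, 12).astype(float)
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            assert spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic)
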