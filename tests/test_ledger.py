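"""Hierarchical uncertainty arithmetic, convergence filter, and report assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

import msmuq
from msmuq.ledger import (
    MSMRecord,
    ParamTuple,
    bayes_stats,
    build_report,
    reduce_seeds,
    group_uncertainty,
    seed_uncertainty,
    shapiro_filter,
    summarize_source,
    uncertainty_factor,
    weighted_mean,
    weighted_std,
)

PARAMS = ParamTuple(tau_tica=5, v_cutoff=0.9, k=25, tau_msm=10, mode="effective")


def make_rec(t, sigma, seed=0, set_id=0, T=1000.0, params=PARAMS, sw=True):
    return MSMRecord(
        params=params, trajectory_set_id=set_id, T_total=T, seed=seed,
        t_B=np.atleast_1d(np.asarray(t, float)),
        sigma_B=np.atleast_1d(np.asarray(sigma, float)),
        sw_pass=sw, sw_W=(0.99, 0.99), n_defined=np.array([100]),
    )


class TestBayesStats:
    def test_identical_samples_have_zero_spread(self):
        t, s = bayes_stats(np.full(10, 2.5))
        assert (t, s) == (2.5, 0.0)

    def test_three_sample_hand_arithmetic(self):
        t, s = bayes_stats(np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(2.0, abs=1e-14)
        assert s == pytest.approx(1.0, abs=1e-14)  # n-1 denominator

    def test_linearity_under_scaling(self):
        base = np.array([0.5, 1.0, 2.0, 2.5])
        t1, s1 = bayes_stats(base)
        t2, s2 = bayes_stats(base * 10)
        assert (t2, s2) == pytest.approx((10 * t1, 10 * s1))

    def test_fewer_than_two_defined_samples_rejected(self):
        with pytest.raises(ValueError):
            bayes_stats(np.array([1.0, np.nan]))


class TestShapiroFilter:
    def test_exact_normal_quantiles_pass(self):
        q = norm.ppf((np.arange(100) + 0.5) / 100)
        passed, W1, W2 = shapiro_filter(np.column_stack([q, q]))
        assert passed and W1 > 0.99

    def test_single_huge_outlier_fails(self):
        rng = np.random.default_rng(0)
        t = rng.normal(1.0, 0.1, size=100)
        t[0] = 50.0  # a >1e4-scale timescale in log10 space dwarfs the rest
        passed, W1, _ = shapiro_filter(t[:, None])
        assert not passed and W1 < 0.95

    def test_vacuous_threshold_passes_everything(self):
        rng = np.random.default_rng(1)
        t = np.exp(rng.normal(size=(50, 2)))  # heavily skewed
        passed, _, _ = shapiro_filter(t, w_crit=0.0)
        assert passed

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            shapiro_filter(np.array([1.0, 2.0])[:, None])


class TestWeightedStatistics:
    def test_weighted_mean_hand_example(self):
        # sigmas (1, 1/sqrt(3)) give weights (1, 3)
        assert weighted_mean([1.0, 3.0], [1.0, 1 / np.sqrt(3)]) == pytest.approx(2.5, abs=1e-14)

    def test_weighted_std_hand_example(self):
        s = weighted_std([1.0, 3.0], [1.0, 1 / np.sqrt(3)])
        assert s == pytest.approx(np.sqrt(0.75), abs=1e-14)

    def test_single_value_mean_and_empty_rejected(self):
        assert weighted_mean([4.2], [0.3]) == 4.2
        with pytest.raises(ValueError):
            weighted_mean([], [])
        with pytest.raises(ValueError):
            weighted_std([1.0], [1.0])

    @given(
        vals=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        sigma=st.floats(0.01, 5.0),
    )
    def test_equal_weights_reduce_to_unweighted_formulas(self, vals, sigma):
        v = np.asarray(vals)
        sigmas = np.full(v.shape, sigma)
        assert weighted_mean(v, sigmas) == pytest.approx(v.mean(), abs=1e-10)
        assert weighted_std(v, sigmas) == pytest.approx(v.std(), abs=1e-10)

    @given(
        pairs=st.lists(
            st.tuples(st.floats(-5, 5), st.floats(0.05, 2.0)),
            min_size=2, max_size=8,
        ),
        perm_seed=st.integers(0, 100),
    )
    def test_permutation_invariance(self, pairs, perm_seed):
        v = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        order = np.random.default_rng(perm_seed).permutation(len(v))
        assert weighted_std(v, s) == pytest.approx(weighted_std(v[order], s[order]), abs=1e-12)
        assert weighted_mean(v, s) == pytest.approx(weighted_mean(v[order], s[order]), abs=1e-12)


class TestSeedUncertainty:
    def test_identical_estimates_have_zero_seed_spread(self):
        recs = [make_rec(2.0, 0.1, seed=i) for i in range(5)]
        sr = seed_uncertainty(recs)
        assert sr.sigma_rs == 0.0
        assert sr.t == 2.0

    def test_two_survivor_hand_arithmetic(self):
        recs = [make_rec(1.0, 1.0, seed=0), make_rec(3.0, 1 / np.sqrt(3), seed=1)]
        sr = seed_uncertainty(recs)
        assert sr.sigma_rs == pytest.approx(np.sqrt(0.75), abs=1e-12)
        assert sr.t == pytest.approx(2.5, abs=1e-12)

    def test_order_invariance_and_filter_exclusion(self):
        recs = [make_rec(1.0, 0.5, seed=0), make_rec(2.0, 0.5, seed=1),
                make_rec(99.0, 0.5, seed=2, sw=False)]
        a = seed_uncertainty(recs)
        b = seed_uncertainty(recs[::-1])
        assert a.t == b.t and a.sigma_rs == b.sigma_rs
        assert a.n_seeds_used == 2  # the filtered record is invisible

    def test_fewer_than_two_usable_records_rejected(self):
        recs = [make_rec(1.0, 0.5, seed=0), make_rec(2.0, 0.5, seed=1, sw=False)]
        with pytest.raises(ValueError):
            seed_uncertainty(recs)


class TestGroupUncertainty:
    def _reduced(self, records):
        reduced, _ = reduce_seeds(records)
        return reduced

    def test_identical_records_give_zero_sigma_everywhere(self):
        recs = [make_rec(2.0, 0.1, seed=s, set_id=i) for i in range(3) for s in range(2)]
        df = group_uncertainty(self._reduced(recs), "trajectory_set")
        assert np.allclose(df["sigma"], 0.0)

    def test_two_set_hand_arithmetic(self):
        # seed groups collapse to (t, sigma_pooled); use degenerate seeds so the
        # pooled sigma equals the Bayes sigma of each group
        recs = [make_rec(1.0, 1.0, seed=s, set_id=0) for s in range(2)]
        recs += [make_rec(3.0, 1 / np.sqrt(3), seed=s, set_id=1) for s in range(2)]
        df = group_uncertainty(self._reduced(recs), "trajectory_set")
        assert len(df) == 1
        assert df["sigma"].iloc[0] == pytest.approx(np.sqrt(0.75), abs=1e-12)

    def test_total_equals_sampling_when_only_sets_vary(self):
        rng = np.random.default_rng(3)
        recs = [
            make_rec(rng.normal(2, 0.3), 0.2, seed=s, set_id=i)
            for i in range(4) for s in range(2)
        ]
        reduced = self._reduced(recs)
        samp = group_uncertainty(reduced, "trajectory_set")
        total = group_uncertainty(reduced, "all")
        assert total["sigma"].iloc[0] == pytest.approx(samp["sigma"].iloc[0], abs=1e-12)

    def test_varying_one_parameter_groups_by_the_others(self):
        recs = []
        for kk, t in ((10, 1.0), (25, 2.0), (50, 3.0)):
            p = PARAMS._replace(k=kk)
            recs += [make_rec(t, 0.2, seed=s, params=p) for s in range(2)]
        df = group_uncertainty(self._reduced(recs), "k")
        assert len(df) == 1 and df["n_group"].iloc[0] == 3
        assert df["source"].iloc[0] == "k"

    def test_undersized_groups_skipped_with_warning(self):
        recs = [make_rec(1.0, 0.2, seed=s, set_id=0) for s in range(2)]
        with pytest.warns(UserWarning):
            df = group_uncertainty(self._reduced(recs), "trajectory_set")
        assert len(df) == 0


class TestSummaries:
    def test_central_66_interval_of_1_to_100(self):
        mean, median, (lo, hi) = summarize_source(np.arange(1.0, 101.0))
        assert lo == pytest.approx(17.83, abs=0.01)
        assert hi == pytest.approx(83.17, abs=0.01)
        assert median == pytest.approx(50.5)

    def test_single_value_degenerate_interval(self):
        mean, median, (lo, hi) = summarize_source([0.7])
        assert mean == median == lo == hi == 0.7

    def test_all_equal_values(self):
        mean, median, (lo, hi) = summarize_source([2.0, 2.0, 2.0])
        assert mean == median == lo == hi == 2.0

    @pytest.mark.parametrize("sigma,factor", [(0.0, 1.0), (0.30103, 2.0), (1.0, 10.0)])
    def test_uncertainty_factor(self, sigma, factor):
        assert uncertainty_factor(sigma) == pytest.approx(factor, abs=1e-5)


class TestFilterRates:
    def test_clean_lognormal_posteriors_mostly_pass(self):
        rng = np.random.default_rng(10)
        passes = sum(
            shapiro_filter(rng.normal(1.0, 0.1, size=(100, 2)))[0]
            for _ in range(100)
        )
        assert passes >= 90

    def test_contaminated_posteriors_mostly_fail(self):
        rng = np.random.default_rng(11)
        fails = 0
        for _ in range(100):
            t = rng.normal(1.0, 0.1, size=(100, 2))
            t[0, 0] = 4.0  # one sample at the 1e4 timescale scale
            fails += not shapiro_filter(t)[0]
        assert fails >= 95


class TestBuildReport:
    def test_hierarchy_sources_present_and_exclusions_counted(self):
        rng = np.random.default_rng(4)
        recs = []
        for kk in (10, 25):
            for set_id in range(3):
                for s in range(2):
                    p = PARAMS._replace(k=kk)
                    recs.append(make_rec(rng.normal(2, 0.2), 0.15, seed=s,
                                         set_id=set_id, params=p))
        recs.append(make_rec(55.0, 0.15, seed=0, set_id=0, sw=False))
        report = build_report(recs)
        assert set(report.ledger["source"]) >= {"bayes", "seed", "sampling", "k", "total"}
        assert report.n_excluded_filter == 1
        assert report.n_records == len(recs)
        assert (report.ledger["sigma"] >= 0).all()
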