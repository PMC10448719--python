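"""Grid orchestration, tipping-point analysis, scaling fits, comparisons."""

import numpy as np
import pytest

import msmuq
from msmuq.ledger import MSMRecord, ParamTuple
from msmuq.scan import (
    ConfigError,
    ScanConfig,
    compare_strategies,
    fit_inverse_sqrt,
    free_exponent_fit,
    parameter_correlation_flags,
    timescale_distributions,
    tipping_point,
)

PARAMS = ParamTuple(tau_tica=2, v_cutoff=0.9, k=8, tau_msm=2, mode="sliding")


def make_rec(t, sigma=0.1, seed=0, set_id=0, T=1000.0, params=PARAMS, sw=True):
    return MSMRecord(
        params=params, trajectory_set_id=set_id, T_total=T, seed=seed,
        t_B=np.atleast_1d(np.asarray(t, float)),
        sigma_B=np.atleast_1d(np.asarray(sigma, float)),
        sw_pass=sw, sw_W=(0.99, 0.99), n_defined=np.array([100]),
    )


@pytest.fixture(scope="module")
def tiny_scan():
    """A 1x1x1x1 grid on a fast small chain: 2 sets, 2 seeds, 3 T values."""
    model = msmuq.build_metastable_chain(3, 0.98, emission_sd=0.15, n_noise_dims=1)
    cfg = ScanConfig(
        tau_tica_grid=[2], v_cutoff_grid=[0.9], k_grid=[6], tau_msm_grid=[2],
        T_list=[2000, 4000, 8000], n_trajectory_sets=2, n_seeds=2,
        n_posterior_samples=30, segment_length=1000.0, mcmc_burnin=2000,
        kmeans_max_iter=20, seed=5,
    )
    records, failures = msmuq.run_scan(model, cfg)
    return model, cfg, records, failures


class TestScanConfig:
    def test_empty_grid_and_bad_values_rejected(self):
        with pytest.raises(ConfigError):
            ScanConfig(k_grid=[])
        with pytest.raises(ConfigError):
            ScanConfig(n_seeds=1)
        with pytest.raises(ConfigError):
            ScanConfig(count_mode="windowed")

    def test_yaml_roundtrip(self, tmp_path):
        cfg = ScanConfig(k_grid=[4, 8], seed=3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        clone = ScanConfig.from_yaml(path)
        assert clone == cfg

    def test_unknown_yaml_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("k_grid: [4]\nn_clusters: 9\n")
        with pytest.raises(ConfigError):
            ScanConfig.from_yaml(path)


class TestRunGrid:
    def test_record_cardinality_matches_grid_product(self, tiny_scan):
        _, cfg, records, failures = tiny_scan
        expected = (
            len(cfg.T_list) * cfg.n_trajectory_sets * cfg.n_seeds
            * len(cfg.tau_tica_grid) * len(cfg.v_cutoff_grid)
            * len(cfg.k_grid) * len(cfg.tau_msm_grid)
        )
        assert len(records) + len(failures) == expected

    def test_rerun_with_same_seed_is_identical(self, tiny_scan):
        model, cfg, records, _ = tiny_scan
        records2, _ = msmuq.run_scan(model, cfg)
        assert len(records) == len(records2)
        for a, b in zip(records, records2):
            assert a.params == b.params and a.seed == b.seed
            np.testing.assert_array_equal(a.t_B, b.t_B)
            np.testing.assert_array_equal(a.sigma_B, b.sigma_B)

    def test_missing_ensembles_rejected_before_work(self, tiny_scan):
        model, cfg, _, _ = tiny_scan
        ensembles = msmuq.generate_scan_ensembles(model, cfg)
        with pytest.raises(ConfigError):
            msmuq.run_grid(cfg, ensembles[:-1])

    def test_report_builds_from_scan_records(self, tiny_scan):
        _, _, records, _ = tiny_scan
        report = msmuq.build_report(records)
        assert {"bayes", "seed"} <= set(report.ledger["source"])
        assert (report.ledger["sigma"] >= 0).all()


class TestTippingPoint:
    def test_interior_maximum_located(self):
        sig = dict(zip((1, 2, 4, 8, 16), (0.05, 0.10, 0.15, 0.106, 0.075)))
        T_tp, flag = tipping_point(sig)
        assert T_tp == 4 and flag is None

    def test_monotone_increasing_flags_beyond_range(self):
        T_tp, flag = tipping_point({1: 0.1, 2: 0.2, 4: 0.3})
        assert T_tp == 4 and flag == "beyond scanned range"

    def test_monotone_decreasing_flags_below_range(self):
        T_tp, flag = tipping_point({1: 0.3, 2: 0.2, 4: 0.1})
        assert T_tp == 1 and flag == "below scanned range"

    def test_tie_takes_smaller_T(self):
        T_tp, _ = tipping_point({1: 0.1, 2: 0.3, 4: 0.3, 8: 0.1})
        assert T_tp == 2


class TestScalingFits:
    def test_exact_inverse_sqrt_data_recovered_with_zero_residual(self):
        sig = {T: 0.3 / np.sqrt(T) for T in (4, 8, 16, 32)}
        fit = fit_inverse_sqrt(sig, 4)
        assert fit.amplitude == pytest.approx(0.3, abs=1e-12)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)
        assert fit.flag is None

    def test_amplitude_scales_linearly_with_sigma(self):
        sig = {T: 0.2 / np.sqrt(T) for T in (4, 8, 16)}
        scaled = {T: 5 * s for T, s in sig.items()}
        a1 = fit_inverse_sqrt(sig, 4).amplitude
        a2 = fit_inverse_sqrt(scaled, 4).amplitude
        assert a2 == pytest.approx(5 * a1, rel=1e-12)

    def test_constant_sigma_raises_misfit_flag(self):
        fit = fit_inverse_sqrt({T: 0.2 for T in (4, 16, 64, 256)}, 4)
        assert fit.flag == "poor inverse-sqrt fit"

    def test_free_exponent_recovers_known_slope(self):
        sig = {T: 1.7 * T**-0.4 for T in (4, 8, 16, 32)}
        slope, amp, resid = free_exponent_fit(sig, 4)
        assert slope == pytest.approx(-0.4, abs=1e-12)
        assert amp == pytest.approx(1.7, rel=1e-10)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_inverse_sqrt({4: 0.1, 8: 0.2}, 8)


def _report_from(sig_by_T, n_sets=4, spread=0.0, seed=0):
    """Build an UncertaintyReport whose sampling sigmas equal sig_by_T."""
    rng = np.random.default_rng(seed)
    recs = []
    for T, sig in sig_by_T.items():
        for set_id in range(n_sets):
            offset = sig if set_id % 2 else -sig  # pairwise spread == sig
            for s in range(2):
                recs.append(make_rec(2.0 + offset + spread * rng.normal(),
                                     0.05, seed=s, set_id=set_id, T=float(T)))
    return msmuq.build_report(recs)


class TestCompareStrategies:
    def test_identical_reports_have_unit_ratios(self):
        sig = {1000: 0.05, 2000: 0.1, 4000: 0.07, 8000: 0.05}
        rep = _report_from(sig)
        cmp = compare_strategies(rep, rep)
        samp = cmp.table[cmp.table["source"] == "sampling"]
        np.testing.assert_allclose(samp["ratio"], 1.0)
        assert cmp.T_tp_multi == cmp.T_tp_single

    def test_doubled_sigma_doubles_ratio(self):
        sig = {1000: 0.05, 2000: 0.1, 4000: 0.07}
        rep_m = _report_from({T: 2 * s for T, s in sig.items()})
        rep_s = _report_from(sig)
        cmp = compare_strategies(rep_m, rep_s)
        samp = cmp.table[cmp.table["source"] == "sampling"]
        np.testing.assert_allclose(samp["ratio"], 2.0, rtol=1e-10)

    def test_disjoint_T_grids_rejected(self):
        rep_a = _report_from({1000: 0.05, 2000: 0.1, 4000: 0.07})
        rep_b = _report_from({3000: 0.05, 6000: 0.1, 9000: 0.07})
        with pytest.raises(ValueError):
            compare_strategies(rep_a, rep_b)


class TestParameterCorrelationFlags:
    def _records_for_k(self, tfunc, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for kk in (10, 25, 50):
            for set_id in range(4):
                p = PARAMS._replace(k=kk)
                recs.append(make_rec(tfunc(kk, rng), 0.05, set_id=set_id, params=p))
        return recs

    def test_independent_timescale_not_flagged(self):
        recs = self._records_for_k(lambda k, rng: 2.0 + 0.01 * rng.normal())
        df = parameter_correlation_flags(recs)
        row = df[(df.parameter == "k")].iloc[0]
        assert not row.flag

    def test_monotone_dependence_flagged(self):
        recs = self._records_for_k(lambda k, rng: 0.1 * k)
        df = parameter_correlation_flags(recs)
        row = df[(df.parameter == "k")].iloc[0]
        assert row.flag and row.rho == pytest.approx(1.0)

    def test_permuted_monotone_case_not_flagged(self):
        rng = np.random.default_rng(1)
        flags = 0
        for trial in range(100):
            recs = self._records_for_k(lambda k, r: 0.1 * k)
            ts = [r.t_B[0] for r in recs]
            perm = rng.permutation(len(ts))
            for rec, idx in zip(recs, perm):
                rec.t_B = np.array([ts[idx]])
            df = parameter_correlation_flags(recs)
            flags += bool(df[(df.parameter == "k")].iloc[0].flag)
        assert flags <= 5

    def test_insufficient_spread_not_evaluable(self):
        recs = [make_rec(2.0, 0.05, set_id=i) for i in range(4)]
        df = parameter_correlation_flags(recs)
        assert not df[(df.parameter == "k")].iloc[0].evaluable


@pytest.fixture(scope="module")
def barrier_scan():
    """Single-trajectory scan on a chain with a deep central bottleneck.

    The weak central link (2% of the normal edge flux) separates fast
    well-sampled lump dynamics from one slow exchange process, so short
    trajectories either see the crossing or not -- the regime in which the
    sampling uncertainty first rises with T and the absolute timescales grow
    systematically as the connected set expands.
    """
    model = msmuq.build_metastable_chain(8, 0.99, bottleneck=0.02)
    cfg = ScanConfig(
        tau_tica_grid=[2], v_cutoff_grid=[0.9], k_grid=[16], tau_msm_grid=[10],
        T_list=[10000, 20000, 40000, 80000, 160000],
        n_trajectory_sets=10, n_seeds=3, n_posterior_samples=50,
        strategy="single", segment_length=10000.0, count_mode="sliding",
        kmeans_max_iter=15, mcmc_burnin=5000, seed=17,
    )
    records, _ = msmuq.run_scan(model, cfg)
    return model, msmuq.build_report(records), records


class TestUndersampledRegime:
    def test_sampling_uncertainty_peaks_at_interior_tipping_point(self, barrier_scan):
        _, report, _ = barrier_scan
        sig = report.sigma_by_T("sampling")
        T_tp, flag = tipping_point(sig)
        T_min = min(sig)
        assert T_tp > T_min  # the maximum is not at the smallest T
        assert sig[T_tp] > sig[T_min]

    def test_median_timescale_grows_systematically_with_T(self, barrier_scan):
        # under-sampling at small T truncates the model to the explored lump,
        # so absolute timescales are systematically short and grow with T
        _, _, records = barrier_scan
        dist = timescale_distributions(records, by="T").sort_values("T")
        medians = dist["median"].to_numpy()
        assert medians[-1] > medians[0] + 0.5  # more than 3x in linear time


class TestTimescaleDistributions:
    def test_single_record_all_quantiles_equal(self):
        df = timescale_distributions([make_rec(2.5)], by="T")
        row = df.iloc[0]
        assert row["q05"] == row["median"] == row["q95"] == 2.5

    def test_median_of_1_to_100(self):
        recs = [make_rec(float(v), set_id=v) for v in range(1, 101)]
        df = timescale_distributions(recs, by="T")
        assert df.iloc[0]["median"] == pytest.approx(50.5)

    def test_constant_key_gives_single_group(self):
        recs = [make_rec(float(v), set_id=v) for v in range(5)]
        df = timescale_distributions(recs, by="k")
        assert len(df) == 1 and df.iloc[0]["n"] == 5

    def test_exclusions_counted_per_group(self):
        recs = [make_rec(2.0), make_rec(3.0, sw=False)]
        df = timescale_distributions(recs, by="T")
        assert df.iloc[0]["n_excluded"] == 1
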