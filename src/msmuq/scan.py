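"""Grid-scan orchestration, scaling-law fits, and strategy comparison.

This module drives the full construction pipeline (tICA -> kinetic-map
projection -> k-means -> counting -> connected-set restriction -> posterior
sampling) over a parameter grid x trajectory sets x clustering seeds,
collects one :class:`~msmuq.ledger.MSMRecord` per construction, and provides
the headline analyses:

* locating the tipping point where the sampling uncertainty peaks before
  decaying with total trajectory length,
* fitting the ``a / sqrt(T)`` decay beyond the tipping point (fixed exponent
  for the amplitude, plus a free-exponent diagnostic refit),
* comparing multi-trajectory against single-trajectory sampling strategies,
* correlation warning flags between construction parameters and absolute
  timescales, and violin-style timescale distribution tables.

The entire scan is a pure function of (config, top seed): every clustering
and sampler seed is derived deterministically from the config seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _st

from . import estimate, ledger, tica
from .cluster import fit_clustering
from .synth import generate_ensemble

__all__ = [
    "ScanConfig",
    "ScalingFit",
    "StrategyComparison",
    "ConfigError",
    "construct_msm",
    "generate_scan_ensembles",
    "run_grid",
    "run_scan",
    "tipping_point",
    "fit_inverse_sqrt",
    "free_exponent_fit",
    "compare_strategies",
    "parameter_correlation_flags",
    "timescale_distributions",
]

logger = logging.getLogger("msmuq.scan")


class ConfigError(ValueError):
    """Invalid scan configuration."""


@dataclass
class ScanConfig:
    """Grid-scan configuration (a desk-scale analog of a full parameter table).

    Grids must be non-empty; ``n_seeds >= 2`` so the random-seed uncertainty
    exists.  ``T_list`` is in physical time (steps x dt of the generator).
    """

    tau_tica_grid: list = field(default_factory=lambda: [2, 5, 10])
    v_cutoff_grid: list = field(default_factory=lambda: [0.8, 0.9, 0.95])
    k_grid: list = field(default_factory=lambda: [10, 25, 50])
    tau_msm_grid: list = field(default_factory=lambda: [5, 10, 20])
    T_list: list = field(default_factory=lambda: [20000 * 2**j for j in range(6)])
    n_trajectory_sets: int = 8
    n_seeds: int = 2
    n_posterior_samples: int = 100
    count_mode: str = "effective"
    strategy: str = "multi"
    segment_length: float = 20000.0
    start_state: int = 0
    seed: int = 0
    n_timescales: int = 2
    w_crit: float = 0.95
    kmeans_max_iter: int = 100
    kmeans_tol: float = 1e-6
    mcmc_burnin: int = 10000
    mcmc_thin: int | None = None

    def __post_init__(self) -> None:
        for name in ("tau_tica_grid", "v_cutoff_grid", "k_grid", "tau_msm_grid", "T_list"):
            if not list(getattr(self, name)):
                raise ConfigError(f"{name} must be non-empty")
        if self.n_seeds < 2:
            raise ConfigError("n_seeds must be >= 2 for the seed uncertainty to exist")
        if self.count_mode not in ("sliding", "effective"):
            raise ConfigError("count_mode must be 'sliding' or 'effective'")
        if self.strategy not in ("multi", "single"):
            raise ConfigError("strategy must be 'multi' or 'single'")
        if self.n_trajectory_sets < 1 or self.n_posterior_samples < 2:
            raise ConfigError("need >= 1 trajectory set and >= 2 posterior samples")

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class ScalingFit:
    """Amplitude fit of ``sigma(T) = a / sqrt(T)`` beyond the tipping point."""

    T_tp: float
    amplitude: float
    residual: float  # rms of log10 residuals
    n_points: int
    flag: str | None = None


@dataclass
class StrategyComparison:
    """Per-(T, source) sigma ratios between sampling strategies."""

    table: pd.DataFrame
    T_tp_multi: float
    T_tp_single: float
    flag_multi: str | None
    flag_single: str | None


def _derived_seed(*entropy) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % 2**31)


def construct_msm(
    trajs,
    tau_tica: int,
    v_cutoff: float,
    k: int,
    tau_msm: int,
    mode: str = "effective",
    cluster_seed: int = 0,
    sampler_seed: int = 0,
    n_posterior_samples: int = 100,
    n_timescales: int = 2,
    kmeans_max_iter: int = 100,
    kmeans_tol: float = 1e-6,
    mcmc_burnin: int = 10000,
    mcmc_thin: int | None = None,
):
    """Run the full construction pipeline once on a set of trajectories.

    Returns a dict with the fitted tICA model, cluster model, discrete
    trajectories, restricted count matrix, reversible MLE, and the posterior
    sample.
    """
    tica_model = tica.fit_tica(trajs, tau_tica, v_cutoff)
    projected = [tica.project_kinetic_map(t, tica_model) for t in trajs]
    cl_model, dtrajs = fit_clustering(
        projected, k, seed=cluster_seed, max_iter=kmeans_max_iter, tol=kmeans_tol
    )
    cm = estimate.count_transitions(dtrajs, tau_msm, mode=mode)
    cm_r = estimate.restrict_to_connected(cm)
    mle = estimate.reversible_mle(cm_r, tol=1e-10)
    posterior = estimate.sample_posterior(
        cm_r,
        n_samples=n_posterior_samples,
        n_burnin=mcmc_burnin,
        n_thin=mcmc_thin,
        seed=sampler_seed,
        n_timescales=n_timescales,
    )
    return {
        "tica": tica_model,
        "clusters": cl_model,
        "dtrajs": dtrajs,
        "counts": cm_r,
        "mle": mle,
        "posterior": posterior,
    }


def generate_scan_ensembles(model, config: ScanConfig):
    """Generate the (T, replicate) trajectory ensembles a config asks for."""
    ensembles = []
    for i_T, T in enumerate(config.T_list):
        seed_T = _derived_seed(config.seed, 101, i_T)
        ens = generate_ensemble(
            model,
            strategy=config.strategy,
            T_total=T,
            segment_length=config.segment_length,
            start_state=config.start_state,
            n_replicates=config.n_trajectory_sets,
            seed=seed_T,
        )
        ensembles.extend(ens)
    return ensembles


def run_grid(config: ScanConfig, ensembles):
    """Run the full grid over every ensemble; returns (records, failures).

    Each construction failure (empty connected set, sampler misconfiguration,
    non-convergence) is logged per parameter tuple and skipped -- the
    scan-level analog of constructions that crash when state occupancies
    approach zero.
    """
    index = {}
    for ens in ensembles:
        index[(float(ens.T_total), ens.replicate_id)] = ens
    for T in config.T_list:
        for rep in range(config.n_trajectory_sets):
            if (float(T), rep) not in index:
                raise ConfigError(f"missing ensemble for T={T}, replicate={rep}")

    records, failures = [], []
    for i_T, T in enumerate(config.T_list):
        t0 = time.perf_counter()
        for rep in range(config.n_trajectory_sets):
            ens = index[(float(T), rep)]
            trajs = ens.trajectories
            for i_tt, tau_tica_v in enumerate(config.tau_tica_grid):
                try:
                    mean, C00, C0t = tica.estimate_covariances(trajs, tau_tica_v)
                    evals, evecs = tica.solve_tica(C00, C0t)
                except (ValueError,) as exc:
                    failures.append({"T": T, "rep": rep, "stage": "tica",
                                     "tau_tica": tau_tica_v, "error": str(exc)})
                    continue
                for i_v, v_cut in enumerate(config.v_cutoff_grid):
                    n_dims = tica.select_dims(evals, v_cut)
                    tmodel = tica.TICAModel(
                        tau_tica=tau_tica_v, mean=mean, C00=C00, C0t_sym=C0t,
                        eigenvalues=evals, eigenvectors=evecs,
                        v_cutoff=v_cut, n_dims=n_dims,
                    )
                    projected = [tica.project_kinetic_map(t, tmodel) for t in trajs]
                    for i_k, k in enumerate(config.k_grid):
                        for s_idx in range(config.n_seeds):
                            cseed = _derived_seed(
                                config.seed, 202, i_T, rep, i_tt, i_v, i_k, s_idx
                            )
                            try:
                                _, dtrajs = fit_clustering(
                                    projected, k, seed=cseed,
                                    max_iter=config.kmeans_max_iter,
                                    tol=config.kmeans_tol,
                                )
                            except (ValueError, AssertionError) as exc:
                                failures.append({"T": T, "rep": rep, "stage": "cluster",
                                                 "k": k, "seed": cseed, "error": str(exc)})
                                continue
                            for i_tm, tau_msm_v in enumerate(config.tau_msm_grid):
                                params = ledger.ParamTuple(
                                    tau_tica=tau_tica_v, v_cutoff=v_cut, k=k,
                                    tau_msm=tau_msm_v, mode=config.count_mode,
                                )
                                pseed = _derived_seed(
                                    config.seed, 303, i_T, rep, i_tt, i_v, i_k, s_idx, i_tm
                                )
                                try:
                                    cm = estimate.count_transitions(
                                        dtrajs, tau_msm_v, mode=config.count_mode
                                    )
                                    cm_r = estimate.restrict_to_connected(cm)
                                    posterior = estimate.sample_posterior(
                                        cm_r,
                                        n_samples=config.n_posterior_samples,
                                        n_burnin=config.mcmc_burnin,
                                        n_thin=config.mcmc_thin,
                                        seed=pseed,
                                        n_timescales=config.n_timescales,
                                    )
                                except (estimate.MSMError, ValueError) as exc:
                                    failures.append(
                                        {"T": T, "rep": rep, "stage": "estimate",
                                         "params": tuple(params), "error": str(exc)}
                                    )
                                    continue
                                rec = ledger.make_record(
                                    posterior, params, rep, float(T), cseed,
                                    w_crit=config.w_crit,
                                    extra={"n_active": cm_r.n_states,
                                           "acceptance": posterior.acceptance_rate},
                                )
                                records.append(rec)
        logger.info("T=%s done in %.1fs (%d records)", T, time.perf_counter() - t0,
                    len(records))
    return records, failures


def run_scan(model, config: ScanConfig):
    """Generate ensembles per config and run the grid on them."""
    ensembles = generate_scan_ensembles(model, config)
    return run_grid(config, ensembles)


def tipping_point(sigma_by_T):
    """Locate the T at which the (mean) sampling uncertainty peaks.

    ``sigma_by_T`` maps T -> summarized sigma.  Returns ``(T_tp, flag)``
    where flag is None for an interior maximum, ``"below scanned range"``
    when the curve decreases from the first point, and
    ``"beyond scanned range"`` when it increases to the last.  Ties pick the
    smallest T.
    """
    items = sorted(sigma_by_T.items())
    if len(items) < 3:
        raise ValueError("need at least 3 values of T")
    Ts = np.array([t for t, _ in items], dtype=float)
    sig = np.array([s for _, s in items], dtype=float)
    i_max = int(np.argmax(sig))  # argmax returns the first (smallest-T) maximum
    flag = None
    if i_max == 0:
        flag = "below scanned range"
    elif i_max == len(Ts) - 1:
        flag = "beyond scanned range"
    return float(Ts[i_max]), flag


def fit_inverse_sqrt(sigma_by_T, T_tp: float) -> ScalingFit:
    """Fit ``sigma = a / sqrt(T)`` over points with T >= T_tp (exponent fixed).

    Only the amplitude is free: ``log10 a = mean(log10 sigma + 0.5 log10 T)``.
    The residual is the rms of log10 residuals; a residual above 0.1 raises a
    misfit flag.
    """
    items = sorted((t, s) for t, s in sigma_by_T.items() if t >= T_tp)
    if len(items) < 2:
        raise ValueError("need at least 2 points with T >= T_tp")
    T = np.array([t for t, _ in items])
    sig = np.array([s for _, s in items])
    if np.any(sig <= 0):
        raise ValueError("sigma values must be positive for the log fit")
    log_a = float(np.mean(np.log10(sig) + 0.5 * np.log10(T)))
    resid = np.log10(sig) - (log_a - 0.5 * np.log10(T))
    rms = float(np.sqrt(np.mean(resid**2)))
    return ScalingFit(
        T_tp=float(T_tp),
        amplitude=float(10.0**log_a),
        residual=rms,
        n_points=len(items),
        flag="poor inverse-sqrt fit" if rms > 0.1 else None,
    )


def free_exponent_fit(sigma_by_T, T_tp: float):
    """Diagnostic OLS refit of ``log10 sigma`` vs ``log10 T`` with free slope.

    Returns ``(slope, amplitude, rms_residual)``; under sufficient sampling
    the slope approaches -1/2.
    """
    items = sorted((t, s) for t, s in sigma_by_T.items() if t >= T_tp)
    if len(items) < 2:
        raise ValueError("need at least 2 points with T >= T_tp")
    x = np.log10([t for t, _ in items])
    y = np.log10([s for _, s in items])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(10.0**intercept), float(np.sqrt(np.mean(resid**2)))


def compare_strategies(
    report_multi: ledger.UncertaintyReport,
    report_single: ledger.UncertaintyReport,
) -> StrategyComparison:
    """Per-T, per-source ratio sigma_multi / sigma_single, plus tipping points.

    Both reports must share the same T grid.  No verdict is attached beyond
    the numbers.
    """
    T_multi = set(report_multi.summaries["T"])
    T_single = set(report_single.summaries["T"])
    if not (T_multi & T_single):
        raise ValueError("reports share no T values")
    if T_multi != T_single:
        raise ValueError("reports must share the same T grid")
    rows = []
    sm = report_multi.summaries.set_index(["T", "source"])["mean"]
    ss = report_single.summaries.set_index(["T", "source"])["mean"]
    for key in sorted(set(sm.index) & set(ss.index)):
        T, source = key
        ratio = sm[key] / ss[key] if ss[key] > 0 else float("nan")
        rows.append(
            {"T": T, "source": source, "sigma_multi": sm[key],
             "sigma_single": ss[key], "ratio": ratio}
        )
    def _tp(report):
        sig = report.sigma_by_T("sampling")
        if len(sig) < 3:
            return float("nan"), "not evaluable (fewer than 3 T values)"
        return tipping_point(sig)

    tp_m, fl_m = _tp(report_multi)
    tp_s, fl_s = _tp(report_single)
    return StrategyComparison(
        table=pd.DataFrame(rows),
        T_tp_multi=tp_m,
        T_tp_single=tp_s,
        flag_multi=fl_m,
        flag_single=fl_s,
    )


def parameter_correlation_flags(
    records, process: int = 0, threshold: float = 0.8
) -> pd.DataFrame:
    """Warning flags for unphysical parameter--timescale correlations.

    For each construction parameter and T, computes the Spearman rank
    correlation between the parameter value and ``t_B``; an absolute
    correlation above ``threshold`` together with monotone per-value medians
    raises a flag.  Parameters spanning fewer than 3 values are marked not
    evaluable.
    """
    rows = []
    usable = [r for r in records if r.usable(process)]
    by_T: dict = {}
    for r in usable:
        by_T.setdefault(r.T_total, []).append(r)
    for T, recs in sorted(by_T.items()):
        for pname in ("tau_tica", "v_cutoff", "k", "tau_msm"):
            vals = np.array([getattr(r.params, pname) for r in recs], dtype=float)
            ts = np.array([r.t_B[process] for r in recs])
            uniq = np.unique(vals)
            if uniq.size < 3:
                rows.append({"parameter": pname, "T": T, "rho": np.nan,
                             "monotone": False, "flag": False, "evaluable": False})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = _st.spearmanr(vals, ts).statistic
            medians = np.array([np.median(ts[vals == u]) for u in uniq])
            dm = np.diff(medians)
            monotone = bool(np.all(dm > 0) or np.all(dm < 0))
            flag = bool(np.isfinite(rho) and abs(rho) >= threshold and monotone)
            rows.append({"parameter": pname, "T": T, "rho": float(rho),
                         "monotone": monotone, "flag": flag, "evaluable": True})
    return pd.DataFrame(rows, columns=["parameter", "T", "rho", "monotone", "flag", "evaluable"])


def timescale_distributions(records, by: str = "T", process: int = 0) -> pd.DataFrame:
    """Quantile tables of ``t_B`` (log10 space) -- machine-readable violins.

    ``by`` is one of ``"T"``, ``"k"``, ``"tau_msm"``.  Quantiles are the 5,
    17, 50, 83, and 95th percentiles; exclusion counts per group are
    included.
    """
    if by not in ("T", "k", "tau_msm"):
        raise ValueError("by must be one of 'T', 'k', 'tau_msm'")
    records = list(records)
    if not records:
        raise ValueError("no records")

    def keyfn(r):
        return r.T_total if by == "T" else getattr(r.params, by)

    groups: dict = {}
    for r in records:
        groups.setdefault(keyfn(r), []).append(r)
    rows = []
    for key, recs in sorted(groups.items()):
        usable = [r for r in recs if r.usable(process)]
        n_excl = len(recs) - len(usable)
        if usable:
            ts = np.array([r.t_B[process] for r in usable])
            q = np.percentile(ts, [5, 17, 50, 83, 95])
        else:
            q = np.full(5, np.nan)
        rows.append(
            {by: key, "q05": q[0], "q17": q[1], "median": q[2], "q83": q[3],
             "q95": q[4], "n": len(usable), "n_excluded": n_excl}
        )
    return pd.DataFrame(rows)
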