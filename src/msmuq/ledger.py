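"""Hierarchical uncertainty quantification for MSM implied timescales.

All uncertainties are spreads of base-10 logarithmic implied timescales
``t' = log10(t)``, so a spread sigma translates to a multiplicative factor
``10**sigma`` in linear time.  The hierarchy is:

1. **Bayes** (``sigma_B``): standard deviation of ``t'`` over the transition
   matrices sampled from the posterior of one constructed MSM.  Records whose
   posterior ``t'`` samples are not approximately normal (Shapiro--Wilk
   ``W < W_crit`` on the longest or second-longest process) are treated as
   unconverged MCMC and excluded from every higher level.
2. **Random seed** (``sigma_RS``): weighted standard deviation of the mean
   posterior log-timescales ``t_B`` over repeats of the construction that
   differ only in the clustering seed.  The repeats are represented upward by
   their weighted mean, carrying a pooled sigma (seed spread and mean Bayes
   sigma added in quadrature).
3. **Sampling / parameter / total** (``sigma_sampling``, ``sigma_param``,
   ``sigma_total``): weighted standard deviations over seed-reduced estimates
   that differ only in the input trajectory set, only in one construction
   parameter, or in everything for a given total length T.  The total is not
   the sum of the parts; no additivity is asserted.

Weights are inverse variances ``w = 1 / max(sigma, sigma_floor)**2``; the
weight rule is a module-level switch (``set_weighting``) so alternatives can
be tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "ParamTuple",
    "MSMRecord",
    "SeedReduced",
    "UncertaintyReport",
    "bayes_stats",
    "shapiro_filter",
    "weighted_mean",
    "weighted_std",
    "seed_uncertainty",
    "reduce_seeds",
    "group_uncertainty",
    "summarize_source",
    "uncertainty_factor",
    "build_report",
    "make_record",
    "set_weighting",
]

SIGMA_FLOOR = 1e-6

_PARAM_NAMES = ("tau_tica", "v_cutoff", "k", "tau_msm")


class ParamTuple(NamedTuple):
    """One construction-parameter combination."""

    tau_tica: int
    v_cutoff: float
    k: int
    tau_msm: int
    mode: str


def _inverse_variance(sigmas: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(sigmas, SIGMA_FLOOR) ** 2


_weight_fn = _inverse_variance


def set_weighting(fn=None):
    """Swap the weight rule (callable sigma-array -> weight-array); None resets."""
    global _weight_fn
    _weight_fn = _inverse_variance if fn is None else fn


@dataclass
class MSMRecord:
    """One constructed MSM: parameters, posterior summary, filter verdict."""

    params: ParamTuple
    trajectory_set_id: int
    T_total: float
    seed: int
    t_B: np.ndarray          # per-process mean posterior log10 timescale
    sigma_B: np.ndarray      # per-process posterior std of log10 timescale
    sw_pass: bool
    sw_W: tuple
    n_defined: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def usable(self, process: int = 0) -> bool:
        return bool(
            self.sw_pass
            and process < len(self.t_B)
            and np.isfinite(self.t_B[process])
        )


@dataclass
class SeedReduced:
    """A seed group reduced to one estimate per (params, set, T)."""

    params: ParamTuple
    trajectory_set_id: int
    T_total: float
    t: float              # weighted mean of t_B over seeds
    sigma_rs: float       # weighted std of t_B over seeds
    sigma_pooled: float   # quadrature of sigma_rs and the mean sigma_B
    n_seeds_used: int


@dataclass
class UncertaintyReport:
    """Tidy ledger of every sigma estimate plus per-(T, source) summaries."""

    ledger: pd.DataFrame      # columns: T, source, varied, fixed, sigma, n_group
    summaries: pd.DataFrame   # columns: T, source, mean, median, lo66, hi66, n
    n_records: int
    n_excluded_filter: int
    n_groups_dropped: int

    def sigma_by_T(self, source: str) -> dict:
        """Map T -> mean sigma for one source (input to tipping-point search)."""
        sub = self.summaries[self.summaries["source"] == source]
        return dict(zip(sub["T"], sub["mean"]))


def bayes_stats(posterior, process_index: int = 0):
    """Mean and (n-1)-denominator std of posterior log-timescales for a process.

    Accepts a :class:`~msmuq.estimate.PosteriorSample` or a plain array of
    ``t'`` samples.  Samples with undefined (NaN) timescales are dropped;
    fewer than 2 defined samples raises ``ValueError`` (record unusable).
    """
    tprime = _extract_tprime(posterior, process_index)
    tprime = tprime[np.isfinite(tprime)]
    if tprime.size < 2:
        raise ValueError("fewer than 2 defined posterior samples for this process")
    return float(np.mean(tprime)), float(np.std(tprime, ddof=1))


def _extract_tprime(posterior, process_index):
    if hasattr(posterior, "log_timescales"):
        arr = np.asarray(posterior.log_timescales)
        if process_index >= arr.shape[1]:
            return np.array([])
        return arr[:, process_index].astype(float)
    return np.asarray(posterior, dtype=float)


def _shapiro_W(samples: np.ndarray) -> float:
    samples = samples[np.isfinite(samples)]
    if samples.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 defined samples")
    if np.ptp(samples) == 0:
        return 1.0  # degenerate but perfectly concentrated: treat as converged
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W, _ = _st.shapiro(samples)
    return float(W)


def shapiro_filter(posterior, w_crit: float = 0.95):
    """Convergence filter on the longest and second-longest log-timescales.

    Returns ``(sw_pass, W_longest, W_second)``.  A heavy-tailed posterior
    sample (unconverged MCMC) collapses W below ``w_crit`` and the record is
    excluded from all higher-level aggregation.  If only one process exists,
    only the longest is tested (W_second is NaN).
    """
    t0 = _extract_tprime(posterior, 0)
    W1 = _shapiro_W(t0)
    t1 = _extract_tprime(posterior, 1)
    t1 = t1[np.isfinite(t1)]
    if t1.size >= 3:
        W2 = _shapiro_W(t1)
        passed = (W1 >= w_crit) and (W2 >= w_crit)
    else:
        W2 = float("nan")
        passed = W1 >= w_crit
    return bool(passed), W1, W2


def weighted_mean(values, sigmas) -> float:
    """Inverse-variance weighted mean, ``w_i = 1/max(sigma_i, floor)^2``."""
    v = np.asarray(values, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != s.shape:
        raise ValueError("values and sigmas must have equal length")
    w = _weight_fn(s)
    return float(np.sum(w * v) / np.sum(w))


def weighted_std(values, sigmas) -> float:
    """Weighted population standard deviation about the weighted mean.

    ``sigma = sqrt( sum w_i (v_i - vbar_w)^2 / sum w_i )``.  With equal
    weights this reduces to the population standard deviation.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if v.size < 2:
        raise ValueError("weighted_std needs at least 2 values")
    w = _weight_fn(s)
    vbar = np.sum(w * v) / np.sum(w)
    return float(np.sqrt(np.sum(w * (v - vbar) ** 2) / np.sum(w)))


def seed_uncertainty(records, process: int = 0):
    """Reduce a group of records differing only in seed.

    Returns a :class:`SeedReduced`; requires >= 2 filter-passing records with
    a defined ``t_B`` for the process, else raises ``ValueError`` (group
    dropped and counted by the caller).
    """
    recs = [r for r in records if r.usable(process)]
    if len(recs) < 2:
        raise ValueError("fewer than 2 usable records in seed group")
    keys = {(r.params, r.trajectory_set_id, r.T_total) for r in recs}
    if len(keys) != 1:
        raise ValueError("seed group mixes parameters or trajectory sets")
    t = np.array([r.t_B[process] for r in recs])
    sb = np.array([r.sigma_B[process] for r in recs])
    sigma_rs = weighted_std(t, sb)
    pooled_t = weighted_mean(t, sb)
    mean_sb = float(np.mean(sb))
    sigma_pooled = float(np.sqrt(sigma_rs**2 + mean_sb**2))
    params, set_id, T = next(iter(keys))
    return SeedReduced(
        params=params,
        trajectory_set_id=set_id,
        T_total=T,
        t=pooled_t,
        sigma_rs=sigma_rs,
        sigma_pooled=sigma_pooled,
        n_seeds_used=len(recs),
    )


def reduce_seeds(records, process: int = 0):
    """Group records by (params, set, T) and reduce each group over seeds.

    Returns ``(list of SeedReduced, n_groups_dropped)``.
    """
    groups: dict = {}
    for r in records:
        groups.setdefault((r.params, r.trajectory_set_id, r.T_total), []).append(r)
    reduced, dropped = [], 0
    for group in groups.values():
        try:
            reduced.append(seed_uncertainty(group, process))
        except ValueError:
            dropped += 1
    return reduced, dropped


def _fixed_key(sr: SeedReduced, vary: str):
    p = sr.params
    if vary == "trajectory_set":
        return (p, sr.T_total)
    if vary == "all":
        return (sr.T_total,)
    if vary in _PARAM_NAMES:
        others = tuple(v for name, v in zip(ParamTuple._fields, p) if name != vary)
        return (others, sr.trajectory_set_id, sr.T_total)
    raise ValueError(f"unknown vary key {vary!r}")


def group_uncertainty(reduced, vary: str) -> pd.DataFrame:
    """Weighted-std spreads over seed-reduced estimates for one varied key.

    ``vary='trajectory_set'`` gives sigma_sampling per fixed parameter tuple
    and T; ``vary`` equal to one parameter name gives sigma_param per fixed
    remaining tuple, set, and T; ``vary='all'`` gives sigma_total per T.
    Groups of size < 2 are skipped with a warning.
    """
    buckets: dict = {}
    for sr in reduced:
        buckets.setdefault(_fixed_key(sr, vary), []).append(sr)
    rows = []
    source = {"trajectory_set": "sampling", "all": "total"}.get(vary, vary)
    for key, members in buckets.items():
        if len(members) < 2:
            warnings.warn(
                f"group of size {len(members)} for vary={vary} skipped", stacklevel=2
            )
            continue
        t = np.array([m.t for m in members])
        s = np.array([m.sigma_pooled for m in members])
        rows.append(
            {
                "T": members[0].T_total,
                "source": source,
                "varied": vary,
                "fixed": repr(key),
                "sigma": weighted_std(t, s),
                "n_group": len(members),
            }
        )
    return pd.DataFrame(rows, columns=["T", "source", "varied", "fixed", "sigma", "n_group"])


def summarize_source(sigmas):
    """Mean, median, and central-66% interval of observed sigma values.

    The interval is the [17th, 83rd] percentile with linear interpolation.
    """
    s = np.asarray(sigmas, dtype=float)
    if s.size == 0:
        raise ValueError("empty input")
    lo, hi = np.percentile(s, [17, 83])
    return float(np.mean(s)), float(np.median(s)), (float(lo), float(hi))


def uncertainty_factor(sigma: float) -> float:
    """Linear-space factor for a log10 spread: ``10**sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(10.0**sigma)


def make_record(
    posterior,
    params: ParamTuple,
    trajectory_set_id: int,
    T_total: float,
    seed: int,
    w_crit: float = 0.95,
    n_processes: int | None = None,
    extra: dict | None = None,
) -> MSMRecord:
    """Summarize a posterior sample into an MSMRecord with the filter verdict."""
    arr = np.asarray(posterior.log_timescales, dtype=float)
    m = arr.shape[1] if n_processes is None else min(n_processes, arr.shape[1])
    t_B = np.full(m, np.nan)
    sigma_B = np.full(m, np.nan)
    n_def = np.zeros(m, dtype=int)
    for p in range(m):
        col = arr[:, p]
        col = col[np.isfinite(col)]
        n_def[p] = col.size
        if col.size >= 2:
            t_B[p] = np.mean(col)
            sigma_B[p] = np.std(col, ddof=1)
    try:
        sw_pass, W1, W2 = shapiro_filter(posterior, w_crit)
    except ValueError:
        sw_pass, W1, W2 = False, float("nan"), float("nan")
    return MSMRecord(
        params=params,
        trajectory_set_id=trajectory_set_id,
        T_total=T_total,
        seed=seed,
        t_B=t_B,
        sigma_B=sigma_B,
        sw_pass=sw_pass,
        sw_W=(W1, W2),
        n_defined=n_def,
        extra=extra or {},
    )


def build_report(records, process: int = 0) -> UncertaintyReport:
    """Assemble the full hierarchical ledger from raw records.

    Bayes sigmas come from individual filter-passing records; seed, sampling,
    parameter, and total sigmas from the reduction hierarchy.  Per-(T, source)
    summaries carry the mean, median, and central-66% interval.
    """
    records = list(records)
    usable = [r for r in records if r.usable(process)]
    n_excluded = len(records) - len(usable)

    rows = []
    for r in usable:
        rows.append(
            {
                "T": r.T_total,
                "source": "bayes",
                "varied": "posterior",
                "fixed": repr((r.params, r.trajectory_set_id, r.seed)),
                "sigma": float(r.sigma_B[process]),
                "n_group": int(r.n_defined[process]) if r.n_defined is not None else -1,
            }
        )
    ledger = pd.DataFrame(rows, columns=["T", "source", "varied", "fixed", "sigma", "n_group"])

    reduced, dropped = reduce_seeds(usable, process)
    seed_rows = pd.DataFrame(
        [
            {
                "T": sr.T_total,
                "source": "seed",
                "varied": "seed",
                "fixed": repr((sr.params, sr.trajectory_set_id)),
                "sigma": sr.sigma_rs,
                "n_group": sr.n_seeds_used,
            }
            for sr in reduced
        ],
        columns=["T", "source", "varied", "fixed", "sigma", "n_group"],
    )
    parts = [ledger, seed_rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parts.append(group_uncertainty(reduced, "trajectory_set"))
        for name in _PARAM_NAMES:
            parts.append(group_uncertainty(reduced, name))
        parts.append(group_uncertainty(reduced, "all"))
    ledger = pd.concat([p for p in parts if len(p)], ignore_index=True)

    summaries = []
    if len(ledger):
        for (T, source), sub in ledger.groupby(["T", "source"]):
            mean, median, (lo, hi) = summarize_source(sub["sigma"].to_numpy())
            summaries.append(
                {"T": T, "source": source, "mean": mean, "median": median,
                 "lo66": lo, "hi66": hi, "n": len(sub)}
            )
    summaries = pd.DataFrame(
        summaries, columns=["T", "source", "mean", "median", "lo66", "hi66", "n"]
    )
    return UncertaintyReport(
        ledger=ledger,
        summaries=summaries,
        n_records=len(records),
        n_excluded_filter=n_excluded,
        n_groups_dropped=dropped,
    )
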