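"""Transition counting, reversible estimation, and Bayesian posterior sampling.

Given discrete trajectories, this module builds the count matrix at a lag
``tau_msm``, restricts it to the largest strongly connected ("reversibly
connected") set of states, computes the reversible maximum-likelihood
transition matrix via the self-consistent symmetric-flux fixed point, and
draws sample transition matrices from the Bayesian posterior
``p(P|C) \\propto prod_ij p_ij^{c_ij}`` restricted to reversible matrices with
the sparsity pattern of ``C + C^T``.

Implied timescales are ``t_m = -tau * dt / ln(lambda_{m+1})`` for the
descending real eigenvalues of the reversible transition matrix, and their
base-10 logarithms ``t' = log10(t)`` are the quantities whose spread defines
every uncertainty in the hierarchical scheme.

Counting modes
--------------
``sliding``
    all overlapping pairs ``(x_t, x_{t+tau})``; overcounts effectively
    independent transitions at lags > 1.
``effective``
    sliding counts globally scaled by ``1/tau`` -- the overlap factor of the
    sliding window -- as a conservative correction for the statistical
    inefficiency of overlapping counts.  Effective counts are real-valued;
    the likelihood accepts non-integer exponents.

Posterior sampler
-----------------
Metropolis--Hastings in the log of the symmetric fluxes ``x_ij = x_ji`` on
the support of ``C + C^T`` (so ``P = X / rowsums(X)`` is reversible by
construction).  The prior is i.i.d. Exponential(1) on the support fluxes,
i.e. the uniform distribution over normalized flux configurations
(Dirichlet(1,...,1) on the support simplex); since ``P`` depends only on the
flux direction, this is the proper realization of a flat prior on the
support.  Proposals multiply one randomly chosen support element by
``exp(N(0, step^2))``; the acceptance ratio includes the log-scale Jacobian.
The step size is adapted to 20--50% acceptance during burn-in and then
frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph

from .cluster import DiscreteTrajectory

__all__ = [
    "CountMatrix",
    "TransitionModel",
    "PosteriorSample",
    "MSMError",
    "ConvergenceError",
    "DisconnectednessError",
    "SamplerError",
    "count_transitions",
    "largest_connected_set",
    "restrict_to_connected",
    "reversible_mle",
    "sample_posterior",
    "implied_timescales",
]

_EIG_ONE_TOL = 1e-12


class MSMError(RuntimeError):
    """Base class for estimation failures."""


class ConvergenceError(MSMError):
    """Fixed-point iteration did not converge within max_iter."""


class DisconnectednessError(MSMError):
    """A non-Perron eigenvalue is numerically 1: the model is disconnected."""


class SamplerError(MSMError):
    """The posterior sampler is misconfigured for this count matrix."""


@dataclass
class CountMatrix:
    """Transition counts at a lag, possibly restricted to the active set."""

    C: np.ndarray
    tau_msm: int
    mode: str
    active_set: np.ndarray | None = None
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")
        if np.any(self.C < 0):
            raise ValueError("C must be non-negative")
        if self.mode not in ("sliding", "effective"):
            raise ValueError("mode must be 'sliding' or 'effective'")

    @property
    def n_states(self) -> int:
        return self.C.shape[0]

    @property
    def n_total(self) -> float:
        return float(self.C.sum())


@dataclass
class TransitionModel:
    """A reversible row-stochastic transition matrix with its spectrum."""

    P: np.ndarray
    stationary: np.ndarray
    tau_msm: int
    dt: float = 1.0
    eigenvalues: np.ndarray = field(init=False)
    timescales: np.ndarray = field(init=False)
    log_timescales: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        pi = np.asarray(self.stationary, dtype=float)
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows of P must sum to 1 within 1e-12")
        flux = pi[:, None] * P
        if np.max(np.abs(flux - flux.T)) > 1e-10:
            raise ValueError("detailed balance violated beyond 1e-10")
        self.eigenvalues = _reversible_spectrum(P, pi)
        self.timescales, self.log_timescales = implied_timescales(
            self.eigenvalues, self.tau_msm, dt=self.dt
        )

    @property
    def n_states(self) -> int:
        return self.P.shape[0]


@dataclass
class PosteriorSample:
    """Transition matrices sampled from the Bayesian posterior.

    ``log_timescales`` is ``(n_samples, m)`` with NaN where a sample's m-th
    eigenvalue was non-positive (undefined timescale, flagged not clipped).
    """

    Ps: np.ndarray  # (n_samples, n, n)
    stationaries: np.ndarray  # (n_samples, n)
    log_timescales: np.ndarray  # (n_samples, m), base-10 log, NaN if undefined
    tau_msm: int
    dt: float
    n_samples: int
    settings: dict
    acceptance_rate: float


def count_transitions(dtrajs, tau_msm: int, mode: str = "sliding") -> CountMatrix:
    """Sliding-window transition counts at lag ``tau_msm``, pooled over trajectories.

    ``effective`` mode divides the sliding counts by ``tau_msm`` (the window
    overlap factor) to correct for the statistical inefficiency of
    overlapping counts; the result is real-valued.
    """
    if tau_msm < 1:
        raise ValueError("tau_msm must be >= 1")
    if mode not in ("sliding", "effective"):
        raise ValueError("mode must be 'sliding' or 'effective'")
    seqs = []
    n_states = 0
    dt = 1.0
    for dtraj in dtrajs:
        s = dtraj.states if isinstance(dtraj, DiscreteTrajectory) else np.asarray(dtraj)
        if isinstance(dtraj, DiscreteTrajectory):
            dt = dtraj.dt
        if s.size:
            n_states = max(n_states, int(s.max()) + 1)
        seqs.append(s)
    usable = [s for s in seqs if s.shape[0] > tau_msm]
    if not usable:
        raise ValueError("all trajectories are shorter than tau_msm + 1")
    C = np.zeros((n_states, n_states))
    for s in usable:
        np.add.at(C, (s[:-tau_msm], s[tau_msm:]), 1.0)
    if mode == "effective":
        C = C / tau_msm
    return CountMatrix(C=C, tau_msm=int(tau_msm), mode=mode, dt=dt)


def largest_connected_set(C) -> np.ndarray:
    """Largest strongly connected component of the count graph.

    Edges are ``i -> j`` wherever ``C_ij > 0``.  Ties between equal-size
    components are broken by the largest total intra-component count, then
    by the lowest smallest member index.  States outside the returned set
    would act as sinks or sources in the MSM and are discarded.
    """
    A = C.C if isinstance(C, CountMatrix) else np.asarray(C, dtype=float)
    if A.size == 0:
        raise ValueError("empty count matrix")
    n = A.shape[0]
    graph = scipy.sparse.csr_matrix((A > 0).astype(np.int8))
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        graph, directed=True, connection="strong"
    )
    best = None
    for comp in range(n_comp):
        members = np.where(labels == comp)[0]
        intra = float(A[np.ix_(members, members)].sum())
        # sort key: larger size, larger intra count, lower smallest index
        key = (len(members), intra, -int(members.min()))
        if best is None or key > best[0]:
            best = (key, members)
    return np.sort(best[1])


def restrict_to_connected(cm: CountMatrix) -> CountMatrix:
    """Restrict a count matrix to its largest strongly connected set."""
    active = largest_connected_set(cm)
    C = cm.C[np.ix_(active, active)]
    return CountMatrix(C=C, tau_msm=cm.tau_msm, mode=cm.mode, active_set=active, dt=cm.dt)


def _reversible_spectrum(P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Real descending eigenvalues via the symmetrized similarity transform."""
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] / sqrt_pi[None, :]) * P
    evals = np.linalg.eigvalsh(0.5 * (S + S.T))
    return evals[::-1]


def implied_timescales(eigenvalues, tau_msm, dt: float = 1.0, n_timescales: int | None = None):
    """Implied timescales and their base-10 logs from descending eigenvalues.

    ``t_m = -tau_msm * dt / ln(lambda_{m+1})``.  Non-positive eigenvalues
    yield NaN (undefined, flagged); an eigenvalue within 1e-12 of 1 beyond
    the Perron root raises :class:`DisconnectednessError`.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    sub = lam[1:] if n_timescales is None else lam[1 : n_timescales + 1]
    if sub.size and np.any(sub >= 1.0 - _EIG_ONE_TOL):
        raise DisconnectednessError(
            "non-Perron eigenvalue numerically 1: disconnected model"
        )
    t = np.full(sub.shape, np.nan)
    pos = sub > 0
    t[pos] = -tau_msm * dt / np.log(sub[pos])
    with np.errstate(invalid="ignore"):
        t_log = np.log10(t)
    return t, t_log


def reversible_mle(cm: CountMatrix, tol: float = 1e-12, max_iter: int = 100000) -> TransitionModel:
    """Reversible maximum-likelihood transition matrix.

    Maximizes ``prod p_ij^{c_ij}`` over reversible row-stochastic matrices by
    the standard self-consistent fixed point on symmetric fluxes,

        ``x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)``,

    iterated until the largest relative flux change drops below ``tol``.
    (The flux change is the stopping variable rather than the likelihood
    change because near the optimum the log-likelihood is flat to machine
    precision long before the matrix itself has converged to 1e-8.)
    Requires a strongly connected count matrix (restrict first).
    """
    C = cm.C if isinstance(cm, CountMatrix) else np.asarray(cm, dtype=float)
    n = C.shape[0]
    if n == 1:
        return TransitionModel(P=np.ones((1, 1)), stationary=np.ones(1),
                               tau_msm=getattr(cm, "tau_msm", 1), dt=getattr(cm, "dt", 1.0))
    Csym = C + C.T
    if np.any((Csym.sum(axis=1)) == 0):
        raise MSMError("count matrix has an all-zero row+column; not connected")
    c_row = C.sum(axis=1)
    support = Csym > 0
    x = Csym / Csym.sum()

    gap = np.inf
    for _ in range(max_iter):
        xs = x.sum(axis=1)
        q = c_row / xs
        denom = q[:, None] + q[None, :]
        x_new = np.where(support, Csym / np.where(support, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(x_new - x) / np.where(support, np.maximum(x, 1e-300), 1.0)
        gap = float(rel[support].max()) if support.any() else 0.0
        x = x_new
        if gap <= tol:
            break
    else:
        raise ConvergenceError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(last relative flux change {gap:.3e})"
        )
    xs = x.sum(axis=1)
    P = x / xs[:, None]
    pi = xs / xs.sum()
    # enforce exact row normalization against accumulated round-off
    P = P / P.sum(axis=1)[:, None]
    return TransitionModel(
        P=P, stationary=pi,
        tau_msm=cm.tau_msm if isinstance(cm, CountMatrix) else 1,
        dt=cm.dt if isinstance(cm, CountMatrix) else 1.0,
    )


def sample_posterior(
    cm: CountMatrix,
    n_samples: int = 100,
    n_burnin: int = 10000,
    n_thin: int | None = None,
    seed: int = 0,
    step: float = 0.2,
    n_timescales: int | None = None,
) -> PosteriorSample:
    """Draw reversible transition matrices from the Bayesian posterior.

    See the module docstring for the sampler construction.  ``n_thin``
    defaults to the support size (one effective sweep between retained
    samples).  Raises :class:`SamplerError` if the post-adaptation acceptance
    rate falls below 1%.
    """
    C = cm.C if isinstance(cm, CountMatrix) else np.asarray(cm, dtype=float)
    tau = cm.tau_msm if isinstance(cm, CountMatrix) else 1
    dt = cm.dt if isinstance(cm, CountMatrix) else 1.0
    n = C.shape[0]
    if n == 1:
        Ps = np.ones((n_samples, 1, 1))
        return PosteriorSample(
            Ps=Ps, stationaries=np.ones((n_samples, 1)),
            log_timescales=np.empty((n_samples, 0)),
            tau_msm=tau, dt=dt, n_samples=n_samples,
            settings={"n_burnin": n_burnin, "n_thin": 1, "seed": seed, "step": 0.0},
            acceptance_rate=1.0,
        )

    mle = reversible_mle(cm, tol=1e-8)  # initialization only; full precision unneeded
    Csym = C + C.T
    iu, ju = np.nonzero(np.triu(Csym) > 0)
    m_sup = iu.size
    if n_thin is None:
        n_thin = m_sup
    n_thin = max(1, int(n_thin))

    # initialize at the MLE flux (x_ij = pi_i * P_ij, symmetric), scaled to sum 1
    Xfull = mle.stationary[:, None] * mle.P
    Xfull = 0.5 * (Xfull + Xfull.T)
    xvals = Xfull[iu, ju]
    xvals = np.maximum(xvals / xvals.sum(), 1e-300)

    # state: full symmetric matrix values via upper-triangle parameterization
    x = xvals.copy()
    s = np.zeros(n)
    for kk in range(m_sup):
        i, j = iu[kk], ju[kk]
        s[i] += x[kk]
        if i != j:
            s[j] += x[kk]
    c_row = C.sum(axis=1)
    cpair = np.array([
        C[iu[kk], ju[kk]] + (C[ju[kk], iu[kk]] if iu[kk] != ju[kk] else 0.0)
        for kk in range(m_sup)
    ])

    rng = np.random.default_rng(seed)
    log = math.log

    iu_l, ju_l = iu.tolist(), ju.tolist()
    x_l = x.tolist()
    s_l = s.tolist()
    cr_l = c_row.tolist()
    cp_l = cpair.tolist()

    def run_phase(n_props, step, adapt):
        nonlocal x_l, s_l
        accepted = 0
        ks = rng.integers(0, m_sup, size=n_props).tolist()
        zs = rng.normal(0.0, 1.0, size=n_props).tolist()
        logu = np.log(rng.random(size=n_props)).tolist()
        win_acc = 0
        for t in range(n_props):
            kk = ks[t]
            z = zs[t] * step
            i = iu_l[kk]
            j = ju_l[kk]
            xo = x_l[kk]
            xn = xo * math.exp(z)
            dx = xn - xo
            si = s_l[i]
            si_n = si + dx
            if si_n <= 0:
                continue
            d = cp_l[kk] * z - cr_l[i] * (log(si_n) - log(si)) - dx + z
            if i != j:
                sj = s_l[j]
                sj_n = sj + dx
                if sj_n <= 0:
                    continue
                d -= cr_l[j] * (log(sj_n) - log(sj))
            if d >= logu[t]:
                x_l[kk] = xn
                s_l[i] = si_n
                if i != j:
                    s_l[j] = sj_n
                accepted += 1
                win_acc += 1
            if adapt and (t + 1) % 200 == 0:
                rate = win_acc / 200.0
                if rate < 0.20:
                    step *= 0.8
                elif rate > 0.50:
                    step *= 1.25
                win_acc = 0
        return accepted, step

    _, step = run_phase(n_burnin, step, adapt=True)

    if n_timescales is None:
        n_timescales = min(8, n - 1)
    m_ts = min(n_timescales, n - 1)
    Ps = np.empty((n_samples, n, n))
    pis = np.empty((n_samples, n))
    t_log = np.full((n_samples, m_ts), np.nan)
    accepted_total = 0
    for snum in range(n_samples):
        acc, _ = run_phase(n_thin, step, adapt=False)
        accepted_total += acc
        X = np.zeros((n, n))
        xv = np.asarray(x_l)
        X[iu, ju] = xv
        X[ju, iu] = xv
        xs = X.sum(axis=1)
        P = X / xs[:, None]
        pi = xs / xs.sum()
        Ps[snum] = P
        pis[snum] = pi
        lam = _reversible_spectrum(P, pi)[1 : m_ts + 1]
        pos = (lam > 0) & (lam < 1.0 - _EIG_ONE_TOL)
        t_log[snum, pos] = np.log10(-tau * dt / np.log(lam[pos]))
    acc_rate = accepted_total / max(1, n_samples * n_thin)
    if acc_rate < 0.01:
        raise SamplerError(
            f"posterior sampler acceptance rate {acc_rate:.4f} < 1% after adaptation"
        )
    return PosteriorSample(
        Ps=Ps,
        stationaries=pis,
        log_timescales=t_log,
        tau_msm=tau,
        dt=dt,
        n_samples=n_samples,
        settings={"n_burnin": n_burnin, "n_thin": n_thin, "seed": seed, "step": step},
        acceptance_rate=acc_rate,
    )
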