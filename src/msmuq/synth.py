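"""Synthetic metastable Markov dynamics with exactly known relaxation timescales.

This module is the ground-truth stand-in for molecular-dynamics input: a
reversible nearest-neighbour (birth--death) Markov chain over a handful of
metastable macrostates, Gaussian emissions into a low-dimensional feature
space, and optional fast-relaxing AR(1) nuisance dimensions.  Because the
chain is built from a symmetric non-negative flux matrix, detailed balance
holds by construction and the implied timescales are known exactly from the
eigendecomposition, so every downstream estimator can be validated against
the truth.

Trajectory ensembles can be generated in two sampling strategies:

``multi``
    many segments of equal length, all started in a common state --
    emulating spawning short simulations from one experimental structure;
``single``
    one long trajectory of the same total length.

All randomness is driven by :class:`numpy.random.SeedSequence` spawning: one
top-level seed deterministically derives one stream per replicate and, within
a replicate, one stream per trajectory for the hidden path and one for the
emission noise.  Runs are therefore bit-reproducible across platforms.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "GroundTruthModel",
    "FeatureTrajectory",
    "TrajectoryEnsemble",
    "build_metastable_chain",
    "sample_discrete_path",
    "emit_features",
    "generate_ensemble",
]

_DB_TOL = 1e-12


@dataclass
class GroundTruthModel:
    """A reversible discrete-state chain with known emissions and timescales.

    Attributes
    ----------
    n_states
        Number of hidden macrostates.
    P_true
        ``(n, n)`` row-stochastic transition matrix per step of ``dt``.
    dt
        Physical time per step (arbitrary units; only ratios matter).
    stationary
        Stationary distribution ``pi`` of ``P_true``.
    emission_means
        ``(n, d_feat)`` emission centres, placed on well-separated lattice
        points.
    emission_sd
        Isotropic Gaussian emission spread per state (one knob controlling
        discretization difficulty).
    n_noise_dims
        Number of appended fast-relaxing nuisance dimensions.
    noise_rho
        Per-step autocorrelation of the AR(1) noise dimensions, in ``[0, 1)``.
    true_timescales
        Implied timescales ``-dt / ln(lambda_{m+1})`` of ``P_true``,
        descending; only the strictly positive eigenvalues contribute.
    seed
        Seed recorded at construction (the build itself is deterministic).
    """

    n_states: int
    P_true: np.ndarray
    dt: float
    stationary: np.ndarray
    emission_means: np.ndarray
    emission_sd: float
    n_noise_dims: int
    noise_rho: float
    true_timescales: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.P_true, dtype=float)
        if P.shape != (self.n_states, self.n_states):
            raise ValueError("P_true shape does not match n_states")
        if np.any(P < 0):
            raise ValueError("P_true has negative entries")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > _DB_TOL:
            raise ValueError("P_true rows must sum to 1 within 1e-12")
        pi = np.asarray(self.stationary, dtype=float)
        flux = pi[:, None] * P
        if np.max(np.abs(flux - flux.T)) > _DB_TOL:
            raise ValueError("detailed balance violated beyond 1e-12")

    @property
    def d_feat(self) -> int:
        return self.emission_means.shape[1]

    @property
    def d_total(self) -> int:
        return self.d_feat + self.n_noise_dims


@dataclass
class FeatureTrajectory:
    """A uniformly sampled continuous feature time series.

    ``values`` is a ``(L, d)`` array with no missing entries, ``dt`` the time
    step, and ``origin`` a free-form replicate/strategy tag.
    """

    values: np.ndarray
    dt: float = 1.0
    origin: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a (L, d) array")
        if v.shape[0] < 2 or v.shape[1] < 1:
            raise ValueError("need L >= 2 frames and d >= 1 features")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite entries")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class TrajectoryEnsemble:
    """A set of feature trajectories sharing one sampling strategy.

    ``strategy`` is ``"multi"`` (many segments from a common start state) or
    ``"single"`` (one long trajectory).  ``T_total`` is the summed physical
    length; ``hidden_paths`` keeps the generating state sequences so tests
    can use oracle discretizations.
    """

    trajectories: list
    strategy: str
    T_total: float
    start_state: int
    replicate_id: int
    seed: int
    hidden_paths: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strategy not in ("multi", "single"):
            raise ValueError("strategy must be 'multi' or 'single'")
        if self.strategy == "single" and len(self.trajectories) != 1:
            raise ValueError("single strategy requires exactly one trajectory")
        total = sum(len(t) * t.dt for t in self.trajectories)
        if not np.isclose(total, self.T_total, rtol=1e-9):
            raise ValueError("T_total does not match summed trajectory length")

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)


def _timescales_from_P(P: np.ndarray, pi: np.ndarray, dt: float) -> np.ndarray:
    """Implied timescales of a reversible P via the symmetrized transform."""
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] / sqrt_pi[None, :]) * P
    evals = np.linalg.eigvalsh(0.5 * (S + S.T))[::-1]
    lam = evals[1:]  # drop the Perron root
    lam = lam[lam > 0]
    ts = -dt / np.log(lam)
    return np.sort(ts)[::-1]


def build_metastable_chain(
    n_macro: int,
    stay_prob: float = 0.995,
    dt: float = 1.0,
    seed: int = 0,
    *,
    emission_sep: float = 1.0,
    emission_sd: float = 0.2,
    n_noise_dims: int = 2,
    noise_rho: float = 0.3,
    layout: str = "zigzag",
    bottleneck: float = 1.0,
) -> GroundTruthModel:
    """Build a reversible nearest-neighbour metastable chain.

    The chain is constructed from a symmetric flux matrix (unit flux on each
    nearest-neighbour edge, diagonal chosen to realize the requested exit
    probability), which guarantees detailed balance.  Each state keeps total
    exit probability ``1 - stay_prob``, split evenly among its neighbours.

    ``bottleneck`` optionally scales the flux of the central edge down
    (0 < bottleneck <= 1).  With a weak central link the chain separates into
    two fast-mixing lumps exchanging over one slow barrier crossing, giving a
    clean timescale gap between the slowest process and the rest -- the
    regime in which sampling uncertainty first rises with trajectory length
    (different trajectory sets explore different sides) and only then decays.
    The default 1.0 keeps the homogeneous chain with its evenly split exit
    probabilities.

    Parameters
    ----------
    n_macro
        Number of macrostates, ``2 <= n_macro <= 50``.
    stay_prob
        Per-step probability of remaining in the current state, in (0, 1).
    dt
        Physical time per step.
    seed
        Recorded on the model; the construction itself is deterministic.
    emission_sep
        Lattice spacing of the emission means.
    emission_sd
        Isotropic emission noise; 0 gives perfectly separable states.
    n_noise_dims, noise_rho
        Count and per-step autocorrelation of AR(1) nuisance dimensions.
    layout
        ``"zigzag"`` places means on a 2-D zig-zag lattice (default),
        ``"line"`` on a 1-D line -- useful for closed-form checks.
    """
    if not 2 <= n_macro <= 50:
        raise ValueError("n_macro must be in [2, 50]")
    if not 0.0 < stay_prob < 1.0:
        raise ValueError("stay_prob must be in (0, 1)")
    if not 0.0 <= noise_rho < 1.0:
        raise ValueError("noise_rho must be in [0, 1)")
    if not 0.0 < bottleneck <= 1.0:
        raise ValueError("bottleneck must be in (0, 1]")

    q = 1.0 - stay_prob
    # Symmetric flux: x_{i,i+1} = 1 on each edge (the central edge scaled by
    # `bottleneck`); the diagonal flux is fixed so that row-normalization
    # yields exit probability q at the ends and q/2 per side in the interior
    # (proportionally less across a bottleneck edge).
    X = np.zeros((n_macro, n_macro))
    for i in range(n_macro - 1):
        w = bottleneck if i == n_macro // 2 - 1 else 1.0
        X[i, i + 1] = X[i + 1, i] = w
    n_nb = (X > 0).sum(axis=1).astype(float)
    target_rowsum = n_nb / q  # ends: 1/q, interior: 2/q
    np.fill_diagonal(X, target_rowsum - X.sum(axis=1))
    rowsum = X.sum(axis=1)
    P = X / rowsum[:, None]
    pi = rowsum / rowsum.sum()

    # irreducibility: the nearest-neighbour chain with positive edge fluxes
    # is irreducible by construction; guard anyway.
    if np.any(P[np.arange(n_macro - 1), np.arange(1, n_macro)] <= 0):
        raise ValueError("construction produced a non-irreducible chain")

    if layout == "line":
        means = (np.arange(n_macro, dtype=float) * emission_sep)[:, None]
    elif layout == "zigzag":
        x = np.arange(n_macro, dtype=float) * emission_sep
        y = (np.arange(n_macro) % 2 - 0.5) * emission_sep
        means = np.column_stack([x, y])
    else:
        raise ValueError(f"unknown emission layout {layout!r}")

    ts = _timescales_from_P(P, pi, dt)
    return GroundTruthModel(
        n_states=n_macro,
        P_true=P,
        dt=dt,
        stationary=pi,
        emission_means=means,
        emission_sd=float(emission_sd),
        n_noise_dims=int(n_noise_dims),
        noise_rho=float(noise_rho),
        true_timescales=ts,
        seed=seed,
    )


def sample_discrete_path(model, length, start, seed=None, rng=None):
    """Sample a hidden-state path of ``length`` steps from ``P_true``.

    Either ``seed`` or an existing ``numpy.random.Generator`` may be given;
    the same seed always yields the same path.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    n = model.n_states
    if not 0 <= start < n:
        raise ValueError(f"start state {start} outside [0, {n})")
    if rng is None:
        rng = np.random.default_rng(seed)
    cum = [row.cumsum().tolist() for row in model.P_true]
    u = rng.random(length - 1)
    states = np.empty(length, dtype=np.int32)
    states[0] = s = int(start)
    bl = bisect_left
    for t, ut in enumerate(u.tolist(), start=1):
        s = bl(cum[s], ut)
        states[t] = s
    return states


def emit_features(path, model, seed=None, rng=None) -> FeatureTrajectory:
    """Emit a feature trajectory for a hidden-state path.

    Each frame is the state's emission mean plus isotropic Gaussian noise of
    scale ``emission_sd``, concatenated with ``n_noise_dims`` independent
    stationary AR(1) series (unit variance, per-step autocorrelation
    ``noise_rho``).
    """
    path = np.asarray(path)
    if path.min() < 0 or path.max() >= model.n_states:
        raise ValueError("path contains invalid state indices")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(path)
    Y = model.emission_means[path].astype(float)
    if model.emission_sd > 0:
        Y = Y + rng.normal(0.0, model.emission_sd, size=Y.shape)
    if model.n_noise_dims > 0:
        rho = model.noise_rho
        innov = rng.normal(size=(L, model.n_noise_dims)) * np.sqrt(1.0 - rho**2)
        z0 = rng.normal(size=model.n_noise_dims)  # stationary start
        Z, _ = lfilter([1.0], [1.0, -rho], innov, axis=0, zi=(rho * z0)[None, :])
        Y = np.hstack([Y, Z])
    return FeatureTrajectory(values=Y, dt=model.dt)


def generate_ensemble(
    model,
    strategy: str,
    T_total: float,
    segment_length: float | None = None,
    start_state: int = 0,
    n_replicates: int = 1,
    seed: int = 0,
) -> list:
    """Generate independent trajectory ensembles of total length ``T_total``.

    ``multi`` splits ``T_total`` into segments of ``segment_length`` physical
    time, all started in ``start_state``; ``single`` produces one trajectory
    of ``T_total``.  Distinct replicates (and trajectories within them) use
    distinct streams spawned from ``seed``.
    """
    if strategy not in ("multi", "single"):
        raise ValueError("strategy must be 'multi' or 'single'")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    steps_total = T_total / model.dt
    if abs(steps_total - round(steps_total)) > 1e-9:
        raise ValueError("T_total must be an integer number of steps")
    steps_total = int(round(steps_total))
    if strategy == "multi":
        if segment_length is None:
            raise ValueError("multi strategy requires segment_length")
        seg_steps = segment_length / model.dt
        if abs(seg_steps - round(seg_steps)) > 1e-9:
            raise ValueError("segment_length must be an integer number of steps")
        seg_steps = int(round(seg_steps))
        if steps_total % seg_steps != 0:
            raise ValueError("T_total must be divisible by segment_length in multi mode")
        lengths = [seg_steps] * (steps_total // seg_steps)
    else:
        lengths = [steps_total]

    top = np.random.SeedSequence(seed)
    rep_seqs = top.spawn(n_replicates)
    ensembles = []
    for rep, rep_seq in enumerate(rep_seqs):
        traj_seqs = rep_seq.spawn(len(lengths))
        trajs, paths = [], []
        for j, (L, tseq) in enumerate(zip(lengths, traj_seqs)):
            path_seq, emit_seq = tseq.spawn(2)
            path = sample_discrete_path(
                model, L, start_state, rng=np.random.default_rng(path_seq)
            )
            traj = emit_features(path, model, rng=np.random.default_rng(emit_seq))
            traj.origin = f"rep{rep}/{strategy}{j}"
            trajs.append(traj)
            paths.append(path)
        ensembles.append(
            TrajectoryEnsemble(
                trajectories=trajs,
                strategy=strategy,
                T_total=float(T_total),
                start_state=start_state,
                replicate_id=rep,
                seed=seed,
                hidden_paths=paths,
            )
        )
    return ensembles
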