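"""k-means++ seeding and Lloyd refinement on kinetic-map projections.

Clustering is the one stochastic element of the construction pipeline: the
seed-to-seed spread of downstream timescale estimates defines the
random-seed uncertainty.  Determinism is therefore a hard contract here --
``(points, k, seed)`` fully determine the fitted model.

Seeding follows the classic D^2-sampling scheme: the first centre is drawn
uniformly from the points, each subsequent centre with probability
proportional to the squared distance to its nearest already-chosen centre.
Lloyd refinement alternates nearest-centre assignment (ties broken by the
lowest centre index) and mean updates; empty clusters are repaired by
re-seeding at the point farthest from its assigned centre, which keeps the
state count k exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import FeatureTrajectory

__all__ = [
    "ClusterModel",
    "DiscreteTrajectory",
    "kmeanspp_seed",
    "lloyd_refine",
    "assign",
    "fit_clustering",
]

_CHUNK = 262144


@dataclass
class ClusterModel:
    """A fitted k-means model: k centres, the seed, and fit diagnostics."""

    k: int
    centers: np.ndarray
    seed: int
    n_iter_run: int
    sse: float

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


@dataclass
class DiscreteTrajectory:
    """Integer state sequence for one source trajectory."""

    states: np.ndarray
    source_id: str = ""
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int32)

    def __len__(self) -> int:
        return self.states.shape[0]


def _labels_and_dist2(X: np.ndarray, centers: np.ndarray):
    """Chunked nearest-centre labels and squared distances (argmin = lowest index)."""
    n = X.shape[0]
    labels = np.empty(n, dtype=np.int32)
    d2min = np.empty(n)
    c2 = np.einsum("ij,ij->i", centers, centers)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        block = X[lo:hi]
        d2 = c2[None, :] - 2.0 * (block @ centers.T)
        lab = np.argmin(d2, axis=1)
        labels[lo:hi] = lab
        d2min[lo:hi] = d2[np.arange(hi - lo), lab] + np.einsum("ij,ij->i", block, block)
    np.maximum(d2min, 0.0, out=d2min)
    return labels, d2min


def kmeanspp_seed(points, k: int, seed=None, rng=None) -> np.ndarray:
    """D^2-sampling initial centres; deterministic under a fixed seed.

    Raises ``ValueError`` if the points contain fewer than ``k`` distinct
    values (detected lazily: the D^2 weights vanish before k centres are
    placed).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    centers = np.empty((k, X.shape[1]))
    first = rng.integers(n)
    centers[0] = X[first]
    d2 = np.einsum("ij,ij->i", X - centers[0], X - centers[0])
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            raise ValueError(
                f"fewer than k={k} distinct points: D^2 weights vanished after {c} centres"
            )
        idx = np.searchsorted(np.cumsum(d2), rng.random() * total)
        idx = min(idx, n - 1)
        centers[c] = X[idx]
        diff2 = np.einsum("ij,ij->i", X - centers[c], X - centers[c])
        np.minimum(d2, diff2, out=d2)
    return centers


def lloyd_refine(points, centers, max_iter: int = 100, tol: float = 1e-6, seed: int = 0) -> ClusterModel:
    """Lloyd iterations from given initial centres.

    Stops when the relative centre shift falls below ``tol`` or after
    ``max_iter`` iterations.  The within-cluster sum of squares (measured at
    each assignment step) is non-increasing; this is asserted on every fit.
    Empty clusters are re-seeded to the point farthest from its assigned
    centre.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    C = np.array(centers, dtype=float, copy=True)
    if C.ndim == 1:
        C = C[:, None]
    k = C.shape[0]
    scale = np.sqrt(np.mean(np.einsum("ij,ij->i", X, X)) + 1e-300)
    prev_sse = np.inf
    sse = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        labels, d2 = _labels_and_dist2(X, C)
        sse = float(d2.sum())
        if sse > prev_sse * (1 + 1e-9) + 1e-12:
            raise AssertionError("Lloyd SSE increased; numerical inconsistency")
        prev_sse = sse
        counts = np.bincount(labels, minlength=k)
        new_C = np.zeros_like(C)
        for j in range(X.shape[1]):
            new_C[:, j] = np.bincount(labels, weights=X[:, j], minlength=k)
        empty = np.where(counts == 0)[0]
        nonzero = counts > 0
        new_C[nonzero] /= counts[nonzero][:, None]
        if empty.size:
            d2work = d2.copy()
            for e in empty:
                far = int(np.argmax(d2work))
                new_C[e] = X[far]
                d2work[far] = 0.0
        shift = np.sqrt(np.sum((new_C - C) ** 2)) / max(scale, 1e-12)
        C = new_C
        if shift < tol:
            break
    labels, d2 = _labels_and_dist2(X, C)
    final_sse = float(d2.sum())
    sse = min(sse, final_sse)
    return ClusterModel(k=k, centers=C, seed=seed, n_iter_run=n_iter, sse=final_sse)


def assign(traj, model: ClusterModel) -> DiscreteTrajectory:
    """Label each frame with its nearest centre (Euclidean; ties -> lowest index)."""
    X = traj.values if isinstance(traj, FeatureTrajectory) else np.asarray(traj, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"frame dimension {X.shape[1]} does not match centre dimension "
            f"{model.centers.shape[1]}"
        )
    labels, _ = _labels_and_dist2(X, model.centers)
    dt = traj.dt if isinstance(traj, FeatureTrajectory) else 1.0
    origin = traj.origin if isinstance(traj, FeatureTrajectory) else ""
    return DiscreteTrajectory(states=labels, source_id=origin, dt=dt)


def fit_clustering(trajs, k: int, seed: int, max_iter: int = 100, tol: float = 1e-6):
    """Pool frames from all trajectories, fit k-means++, assign per trajectory.

    Returns ``(ClusterModel, [DiscreteTrajectory, ...])``.
    """
    arrays = [t.values if isinstance(t, FeatureTrajectory) else np.asarray(t, float) for t in trajs]
    X = np.vstack(arrays)
    rng = np.random.default_rng(seed)
    init = kmeanspp_seed(X, k, rng=rng)
    model = lloyd_refine(X, init, max_iter=max_iter, tol=tol, seed=seed)
    dtrajs = [assign(t, model) for t in trajs]
    return model, dtrajs
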