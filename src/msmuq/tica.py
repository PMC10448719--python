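"""Time-lagged independent component analysis with kinetic-map rescaling.

tICA solves the generalized eigenproblem ``C_0t v = lambda C_00 v`` for the
instantaneous covariance ``C_00`` and the symmetrized time-lagged covariance
``C_0t`` of a feature time series at lag ``tau_tica``.  Eigenvectors are the
slowest linear collective coordinates; projecting onto them and rescaling by
the eigenvalues yields the kinetic map, in which Euclidean distance
approximates kinetic distance.  Dimension selection uses a cumulative
kinetic-variance cutoff based on squared eigenvalues.

The time-lagged covariance is symmetrized, ``(C_0t + C_0t^T)/2``, so the
eigenpairs are real; the frame mean and ``C_00`` are estimated from exactly
the frames that enter lagged pairs (each pair contributes its head and its
tail frame), keeping the two covariances consistently paired.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .synth import FeatureTrajectory

__all__ = [
    "TICAModel",
    "estimate_covariances",
    "solve_tica",
    "select_dims",
    "project_kinetic_map",
    "fit_tica",
]


@dataclass
class TICAModel:
    """A fitted tICA model with kinetic-map projection parameters."""

    tau_tica: int
    mean: np.ndarray
    C00: np.ndarray
    C0t_sym: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, normalized v^T C00 v = 1
    v_cutoff: float
    n_dims: int

    def to_json(self) -> str:
        payload = {
            "tau_tica": int(self.tau_tica),
            "mean": self.mean.tolist(),
            "C00": self.C00.tolist(),
            "C0t_sym": self.C0t_sym.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "v_cutoff": float(self.v_cutoff),
            "n_dims": int(self.n_dims),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TICAModel":
        d = json.loads(text)
        return cls(
            tau_tica=d["tau_tica"],
            mean=np.array(d["mean"]),
            C00=np.array(d["C00"]),
            C0t_sym=np.array(d["C0t_sym"]),
            eigenvalues=np.array(d["eigenvalues"]),
            eigenvectors=np.array(d["eigenvectors"]),
            v_cutoff=d["v_cutoff"],
            n_dims=d["n_dims"],
        )


def _traj_values(traj) -> np.ndarray:
    if isinstance(traj, FeatureTrajectory):
        return traj.values
    return np.asarray(traj, dtype=float)


def estimate_covariances(trajs, tau_tica: int):
    """Pooled mean, instantaneous and symmetrized lagged covariance.

    All within-trajectory pairs ``(x_t, x_{t+tau})`` are pooled across
    trajectories.  Trajectories shorter than ``tau_tica + 1`` are skipped
    with a warning; if all are skipped, a ``ValueError`` is raised.

    Returns ``(mean, C00, C0t_sym)``.
    """
    if tau_tica < 1:
        raise ValueError("tau_tica must be >= 1")
    n_pairs = 0
    sum_frames = None
    s00 = s0t = None
    d = None
    n_used = 0
    for traj in trajs:
        X = _traj_values(traj)
        if d is None:
            d = X.shape[1]
        elif X.shape[1] != d:
            raise ValueError("inconsistent trajectory dimensionality")
        if X.shape[0] <= tau_tica:
            warnings.warn(
                f"trajectory of length {X.shape[0]} <= tau_tica={tau_tica} skipped",
                stacklevel=2,
            )
            continue
        X0 = X[:-tau_tica]
        Xt = X[tau_tica:]
        if sum_frames is None:
            sum_frames = np.zeros(d)
            s00 = np.zeros((d, d))
            s0t = np.zeros((d, d))
        sum_frames += X0.sum(axis=0) + Xt.sum(axis=0)
        s00 += X0.T @ X0 + Xt.T @ Xt
        s0t += X0.T @ Xt
        n_pairs += X0.shape[0]
        n_used += 1
    if n_used == 0:
        raise ValueError("no trajectory longer than tau_tica; cannot estimate covariances")
    mean = sum_frames / (2 * n_pairs)
    C00 = s00 / (2 * n_pairs) - np.outer(mean, mean)
    C0t = s0t / n_pairs - np.outer(mean, mean)
    C0t_sym = 0.5 * (C0t + C0t.T)
    C00 = 0.5 * (C00 + C00.T)
    return mean, C00, C0t_sym


def solve_tica(C00, C0t_sym, reg_eps: float | None = None):
    """Solve ``C0t_sym v = lambda C00 v`` with diagonal regularization.

    ``reg_eps`` defaults to ``1e-10 * trace(C00) / d``; it is added to the
    diagonal of ``C00`` before the generalized symmetric solve so degenerate
    features do not abort a parameter scan.  Returns descending eigenvalues
    and eigenvectors (columns) normalized to ``v^T C00 v = 1``.
    """
    C00 = np.asarray(C00, dtype=float)
    C0t_sym = np.asarray(C0t_sym, dtype=float)
    d = C00.shape[0]
    if reg_eps is None:
        reg_eps = 1e-10 * np.trace(C00) / d
    C00r = C00 + reg_eps * np.eye(d)
    try:
        evals, evecs = scipy.linalg.eigh(C0t_sym, C00r)
    except scipy.linalg.LinAlgError as exc:
        bad = np.where(np.diag(C00) <= 0)[0]
        raise ValueError(
            f"C00 numerically singular even after regularization "
            f"(suspect dimensions: {bad.tolist()})"
        ) from exc
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def select_dims(eigenvalues, v_cutoff: float) -> int:
    """Smallest dimension count reaching cumulative kinetic variance >= cutoff.

    Kinetic variance of component ``i`` is ``lambda_i^2 / sum_j lambda_j^2``
    (eigenvalues taken in descending order; negative eigenvalues still
    contribute their square).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("no eigenvalues")
    if not 0.0 < v_cutoff <= 1.0:
        raise ValueError("v_cutoff must be in (0, 1]")
    total = np.sum(lam**2)
    if total == 0:
        raise ValueError("all eigenvalues are zero: no kinetic content")
    cum = np.cumsum(lam**2) / total
    # guard against round-off just below 1.0 at the last entry
    cum[-1] = max(cum[-1], 1.0)
    return int(np.searchsorted(cum, v_cutoff - 1e-12) + 1)


def project_kinetic_map(traj, model: TICAModel) -> FeatureTrajectory:
    """Project a trajectory onto the kinetic map of a fitted model.

    Output coordinate ``i`` is ``lambda_i * v_i^T (x - mean)`` for the first
    ``n_dims`` eigenpairs, so Euclidean distances in the projection
    approximate kinetic distances.
    """
    X = _traj_values(traj)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"trajectory dimension {X.shape[1]} does not match model "
            f"dimension {model.mean.shape[0]}"
        )
    m = model.n_dims
    V = model.eigenvectors[:, :m]
    lam = model.eigenvalues[:m]
    Y = (X - model.mean) @ V * lam
    dt = traj.dt if isinstance(traj, FeatureTrajectory) else 1.0
    origin = traj.origin if isinstance(traj, FeatureTrajectory) else ""
    return FeatureTrajectory(values=Y, dt=dt, origin=origin)


def fit_tica(trajs, tau_tica: int, v_cutoff: float, reg_eps: float | None = None) -> TICAModel:
    """Convenience: estimate covariances, solve, and select dimensions."""
    mean, C00, C0t_sym = estimate_covariances(trajs, tau_tica)
    evals, evecs = solve_tica(C00, C0t_sym, reg_eps)
    n_dims = select_dims(evals, v_cutoff)
    return TICAModel(
        tau_tica=int(tau_tica),
        mean=mean,
        C00=C00,
        C0t_sym=C0t_sym,
        eigenvalues=evals,
        eigenvectors=evecs,
        v_cutoff=float(v_cutoff),
        n_dims=n_dims,
    )
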