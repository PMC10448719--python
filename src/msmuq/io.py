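"""Plain-text serialization: trajectories, discrete trajectories, ledgers.

Feature trajectories are TSV files with a header row naming columns
``t, f0..f{d-1}``; ensembles get a JSON manifest listing the files, the
strategy, total length, seed, and (when available) the generator's true
timescales.  Discrete trajectories are one integer per line with a JSON
sidecar.  Records and ledgers are tidy TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterModel, DiscreteTrajectory
from .estimate import CountMatrix
from .ledger import MSMRecord, ParamTuple, UncertaintyReport
from .synth import FeatureTrajectory, TrajectoryEnsemble

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_ensemble",
    "read_ensemble",
    "write_dtraj",
    "read_dtraj",
    "write_cluster_model",
    "write_count_matrix",
    "read_count_matrix",
    "write_posterior_log_timescales",
    "records_to_frame",
    "write_records",
    "read_records",
    "write_report",
]


def write_trajectory(traj: FeatureTrajectory, path) -> None:
    path = Path(path)
    d = traj.d
    t = np.arange(len(traj)) * traj.dt
    df = pd.DataFrame(
        np.column_stack([t, traj.values]),
        columns=["t"] + [f"f{i}" for i in range(d)],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trajectory(path) -> FeatureTrajectory:
    df = pd.read_csv(path, sep="\t")
    t = df["t"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    values = df.drop(columns="t").to_numpy(dtype=float)
    return FeatureTrajectory(values=values, dt=dt, origin=str(path))


def write_ensemble(ensemble: TrajectoryEnsemble, out_dir, true_timescales=None) -> Path:
    """One TSV per trajectory plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, traj in enumerate(ensemble.trajectories):
        name = f"traj_{ensemble.replicate_id:03d}_{i:04d}.tsv"
        write_trajectory(traj, out_dir / name)
        files.append(name)
    manifest = {
        "files": files,
        "strategy": ensemble.strategy,
        "T_total": ensemble.T_total,
        "start_state": ensemble.start_state,
        "replicate_id": ensemble.replicate_id,
        "seed": ensemble.seed,
        "true_timescales": (
            list(map(float, true_timescales)) if true_timescales is not None else None
        ),
    }
    mpath = out_dir / f"manifest_{ensemble.replicate_id:03d}.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_ensemble(manifest_path) -> TrajectoryEnsemble:
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    trajs = [read_trajectory(mpath.parent / name) for name in manifest["files"]]
    return TrajectoryEnsemble(
        trajectories=trajs,
        strategy=manifest["strategy"],
        T_total=manifest["T_total"],
        start_state=manifest["start_state"],
        replicate_id=manifest["replicate_id"],
        seed=manifest["seed"],
    )


def write_dtraj(dtraj: DiscreteTrajectory, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    np.savetxt(path, dtraj.states, fmt="%d")
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_dtraj(path) -> DiscreteTrajectory:
    states = np.loadtxt(path, dtype=np.int32, ndmin=1)
    return DiscreteTrajectory(states=states, source_id=str(path))


def write_cluster_model(model: ClusterModel, path) -> None:
    """Centres as TSV plus a JSON sidecar with k, seed, and fit diagnostics."""
    path = Path(path)
    np.savetxt(path, model.centers, delimiter="\t", fmt="%.10g")
    Path(str(path) + ".json").write_text(json.dumps({
        "k": int(model.k),
        "seed": int(model.seed),
        "n_iter_run": int(model.n_iter_run),
        "sse": float(model.sse),
        "center_file": path.name,
    }))


def write_count_matrix(cm: CountMatrix, path) -> None:
    """Dense TSV plus a JSON sidecar with lag, mode, and the active set."""
    path = Path(path)
    np.savetxt(path, cm.C, delimiter="\t", fmt="%.10g")
    Path(str(path) + ".json").write_text(json.dumps({
        "tau_msm": int(cm.tau_msm),
        "mode": cm.mode,
        "dt": cm.dt,
        "active_set": None if cm.active_set is None else cm.active_set.tolist(),
    }))


def read_count_matrix(path) -> CountMatrix:
    path = Path(path)
    C = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(Path(str(path) + ".json").read_text())
    active = meta["active_set"]
    return CountMatrix(
        C=C, tau_msm=meta["tau_msm"], mode=meta["mode"], dt=meta["dt"],
        active_set=None if active is None else np.asarray(active),
    )


def write_posterior_log_timescales(posterior, path) -> None:
    """Posterior t' samples, one column per process, as TSV."""
    arr = np.asarray(posterior.log_timescales)
    df = pd.DataFrame(arr, columns=[f"process_{p}" for p in range(arr.shape[1])])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "tau_tica": r.params.tau_tica,
            "v_cutoff": r.params.v_cutoff,
            "k": r.params.k,
            "tau_msm": r.params.tau_msm,
            "mode": r.params.mode,
            "trajectory_set_id": r.trajectory_set_id,
            "T_total": r.T_total,
            "seed": r.seed,
            "sw_pass": r.sw_pass,
            "sw_W1": r.sw_W[0],
            "sw_W2": r.sw_W[1],
        }
        for p in range(len(r.t_B)):
            row[f"t_B_{p}"] = r.t_B[p]
            row[f"sigma_B_{p}"] = r.sigma_B[p]
        rows.append(row)
    return pd.DataFrame(rows)


def write_records(records, path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records(path):
    """Read records written by :func:`write_records` back into MSMRecords."""
    df = pd.read_csv(path, sep="\t")
    n_proc = sum(1 for c in df.columns if c.startswith("t_B_"))
    records = []
    for _, row in df.iterrows():
        params = ParamTuple(
            tau_tica=int(row["tau_tica"]),
            v_cutoff=float(row["v_cutoff"]),
            k=int(row["k"]),
            tau_msm=int(row["tau_msm"]),
            mode=str(row["mode"]),
        )
        t_B = np.array([row[f"t_B_{p}"] for p in range(n_proc)], dtype=float)
        s_B = np.array([row[f"sigma_B_{p}"] for p in range(n_proc)], dtype=float)
        records.append(
            MSMRecord(
                params=params,
                trajectory_set_id=int(row["trajectory_set_id"]),
                T_total=float(row["T_total"]),
                seed=int(row["seed"]),
                t_B=t_B,
                sigma_B=s_B,
                sw_pass=bool(row["sw_pass"]),
                sw_W=(float(row["sw_W1"]), float(row["sw_W2"])),
            )
        )
    return records


def write_report(report: UncertaintyReport, out_dir) -> None:
    """Ledger TSV plus a JSON summary with exclusion counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.ledger.to_csv(out_dir / "ledger.tsv", sep="\t", index=False)
    report.summaries.to_csv(out_dir / "summaries.tsv", sep="\t", index=False)
    meta = {
        "n_records": report.n_records,
        "n_excluded_filter": report.n_excluded_filter,
        "n_groups_dropped": report.n_groups_dropped,
    }
    (out_dir / "report.json").write_text(json.dumps(meta, indent=1))
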