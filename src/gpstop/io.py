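"""Plain-text session and result formats.

Events CSV: one row per trial with columns ``trial_id, condition,
go_direction, choice, t_center_in, t_go, ssd, t_center_out, t_side_in,
rewarded`` (empty fields where an event did not occur; times in seconds on
the session clock).  Spikes CSV: ``unit_id, spike_time`` rows.  Ground truth
and analysis reports are JSON; fitted models are a JSON header plus a CSV
weight matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TrialRecord
from .statespace import AxisSet, StateSpaceModel, Trajectory
from .synth import GroundTruth

__all__ = [
    "write_events_csv", "read_events_csv",
    "write_spikes_csv", "read_spikes_csv",
    "write_ground_truth", "read_ground_truth",
    "save_model", "load_model",
    "trajectory_frame",
]

_EVENT_COLS = ["trial_id", "condition", "go_direction", "choice",
               "t_center_in", "t_go", "ssd", "t_center_out", "t_side_in", "rewarded"]


def write_events_csv(path: str | Path, trials: list[TrialRecord]) -> None:
    rows = [{c: getattr(t, c) for c in _EVENT_COLS} for t in trials]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    trials = []
    for _, r in df.iterrows():
        def opt(x):
            return None if pd.isna(x) else float(x)
        trials.append(TrialRecord(
            trial_id=int(r.trial_id), condition=str(r.condition),
            go_direction=str(r.go_direction),
            choice=(None if ("choice" not in df.columns or pd.isna(r.get("choice"))) else str(r.choice)),
            t_center_in=float(r.t_center_in), t_go=float(r.t_go),
            ssd=opt(r.ssd), t_center_out=opt(r.t_center_out), t_side_in=opt(r.t_side_in),
            rewarded=bool(r.rewarded)))
    return trials


def write_spikes_csv(path: str | Path, spikes: dict[int, np.ndarray]) -> None:
    parts = [pd.DataFrame({"unit_id": uid, "spike_time": np.asarray(t)})
             for uid, t in sorted(spikes.items())]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_spikes_csv(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {int(uid): g.spike_time.to_numpy(dtype=float)
            for uid, g in df.groupby("unit_id")}


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    Path(path).write_text(json.dumps(gt.to_dict()))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())

    def arr(x, dtype=float):
        return None if x is None else np.asarray(x, dtype=dtype)

    return GroundTruth(
        go_finish=arr(d["go_finish"]), stop_finish=arr(d["stop_finish"]),
        scheduled_stop=arr(d["scheduled_stop"], bool), converted=arr(d["converted"], bool),
        choice_sign=arr(d["choice_sign"]), move_onset=arr(d["move_onset"]),
        move_end=arr(d["move_end"]), halt_time=arr(d["halt_time"]),
        trial_start=arr(d["trial_start"]), trial_end=arr(d["trial_end"]),
        pre_go_state_offsets={k: tuple(v) for k, v in d["pre_go_state_offsets"].items()},
        baseline_rates=arr(d["baseline_rates"]), init_loadings=arr(d["init_loadings"]),
        sel_loadings=arr(d["sel_loadings"]))


def save_model(outdir: str | Path, model: StateSpaceModel, axes: AxisSet | None = None) -> None:
    """Serialize a fitted model: JSON header + weight/column-mean CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = {
        "space": model.space,
        "k": int(model.k),
        "variance_explained": model.variance_explained.tolist(),
        "unit_ids": model.unit_ids.tolist(),
    }
    if axes is not None:
        header["axes"] = {
            "a0": axes.a0.tolist(), "a1": axes.a1.tolist(),
            "m_contra": axes.m_contra.tolist(), "m_ipsi": axes.m_ipsi.tolist(),
            "space": axes.space,
        }
    (outdir / "model.json").write_text(json.dumps(header, indent=2))
    np.savetxt(outdir / "weights.csv", model.W, delimiter=",")
    np.savetxt(outdir / "column_means.csv", model.column_means, delimiter=",")
    np.savetxt(outdir / "scores.csv", model.S, delimiter=",")


def load_model(outdir: str | Path) -> tuple[StateSpaceModel, AxisSet | None]:
    outdir = Path(outdir)
    header = json.loads((outdir / "model.json").read_text())
    W = np.loadtxt(outdir / "weights.csv", delimiter=",", ndmin=2)
    model = StateSpaceModel(
        W=W,
        S=np.loadtxt(outdir / "scores.csv", delimiter=",", ndmin=2),
        variance_explained=np.asarray(header["variance_explained"]),
        column_means=np.loadtxt(outdir / "column_means.csv", delimiter=","),
        unit_ids=np.asarray(header["unit_ids"]),
        space=header["space"])
    axes = None
    if "axes" in header:
        a = header["axes"]
        axes = AxisSet(a0=np.asarray(a["a0"]), a1=np.asarray(a["a1"]),
                       m_contra=np.asarray(a["m_contra"]), m_ipsi=np.asarray(a["m_ipsi"]),
                       space=a["space"])
    return model, axes


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy CSV-ready frame: time, PC1..PCK, initiation/selection coords."""
    cols = {"time": traj.times}
    for k in range(traj.positions.shape[1]):
        cols[f"pc{k + 1}"] = traj.positions[:, k]
    if traj.initiation is not None:
        cols["initiation_coord"] = traj.initiation
    if traj.selection is not None:
        cols["selection_coord"] = traj.selection
    return pd.DataFrame(cols)
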