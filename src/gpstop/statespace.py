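"""Population state space: PCA over condition-averaged rates and named axes.

The population activity matrix R stacks, for every unit, the Z-scored
condition-averaged rate in a 500 ms window around movement onset (Center
Out), for contra then ipsi movements: R is (T*C, N) with T = 251 timepoints
at 2 ms and C = 2 conditions.  Columns are mean-centered, PCA is computed by
SVD, and the scores are S = R W with W the right singular vectors.

Two behaviorally-anchored axes are then defined in the (default 10-D) score
space:

* Initiation Axis — from the mean position at the Go cue (scaled coordinate
  0) to the mean position at Center Out (coordinate 1): progression toward
  movement onset.
* Selection Axis — between the ipsi (-1) and contra (+1) trajectory means:
  bias toward one movement direction.

A full-dimensional variant defines the same axes directly on the N-D mean
rate vectors (identity weights), skipping the PCA step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rates import AlignedTensor, condition_average

__all__ = [
    "PopulationMatrix",
    "StateSpaceModel",
    "AxisSet",
    "Trajectory",
    "DegenerateAxisError",
    "build_population_matrix",
    "fit_pca",
    "full_space_model",
    "define_axes",
    "axes_from_tensors",
    "project_alignment",
]

log = logging.getLogger("gpstop")


class DegenerateAxisError(ValueError):
    """Axis anchors coincide; the axis direction is undefined."""


@dataclass
class PopulationMatrix:
    """Centered condition-averaged population matrix R (T*C rows, N columns)."""

    R: np.ndarray                  # centered, (T*C, N)
    column_means: np.ndarray       # (N,), subtracted from the raw matrix
    times: np.ndarray              # (T,) relative time grid
    conditions: tuple[str, ...]    # row-block order, e.g. ("contra", "ipsi")
    unit_ids: np.ndarray

    @property
    def n_time(self) -> int:
        return self.times.size

    @property
    def n_units(self) -> int:
        return self.R.shape[1]

    def block(self, condition: str) -> np.ndarray:
        """Centered (T, N) rows of one condition."""
        i = self.conditions.index(condition)
        return self.R[i * self.n_time: (i + 1) * self.n_time]


@dataclass
class StateSpaceModel:
    """PCA (or identity) weights and scores over the population matrix."""

    W: np.ndarray                  # (N, K) orthonormal columns
    S: np.ndarray                  # (T*C, K) scores, S = R W
    variance_explained: np.ndarray # per component, fraction of total
    column_means: np.ndarray       # (N,), applied before projecting
    unit_ids: np.ndarray
    space: str = "pc"              # "pc" or "full"
    sign_flips: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def project(self, z: np.ndarray) -> np.ndarray:
        """Project raw (..., N) Z-rate vectors into the model space."""
        return (np.asarray(z, dtype=float) - self.column_means) @ self.W

    def project_difference(self, dz: np.ndarray) -> np.ndarray:
        """Project condition differences (centering cancels)."""
        return np.asarray(dz, dtype=float) @ self.W


@dataclass
class AxisSet:
    """Initiation and Selection axes with their affine scalings.

    Scaled coordinates: Go-cue anchor -> 0 and Center-Out anchor -> 1 on the
    Initiation Axis; ipsi-trajectory mean -> -1 and contra-trajectory mean ->
    +1 on the Selection Axis.
    """

    a0: np.ndarray                 # mean position at Go cue
    a1: np.ndarray                 # mean position at Center Out
    m_contra: np.ndarray           # contra-trajectory mean
    m_ipsi: np.ndarray             # ipsi-trajectory mean
    space: str = "pc"

    def __post_init__(self) -> None:
        if not np.any(self.initiation_direction):
            raise DegenerateAxisError("Go-cue and Center-Out anchors coincide")
        if not np.any(self.selection_direction):
            raise DegenerateAxisError("contra and ipsi trajectory means coincide")

    @property
    def initiation_direction(self) -> np.ndarray:
        return self.a1 - self.a0

    @property
    def selection_direction(self) -> np.ndarray:
        return self.m_contra - self.m_ipsi

    def initiation_coord(self, pos: np.ndarray) -> np.ndarray:
        """Scaled Initiation-Axis coordinate of positions (..., K)."""
        d = self.initiation_direction
        return (np.asarray(pos) - self.a0) @ d / (d @ d)

    def selection_coord(self, pos: np.ndarray) -> np.ndarray:
        """Scaled Selection-Axis coordinate of positions (..., K)."""
        e = self.selection_direction
        mid = 0.5 * (self.m_contra + self.m_ipsi)
        return 2.0 * ((np.asarray(pos) - mid) @ e) / (e @ e)

    def initiation_delta(self, dpos: np.ndarray) -> np.ndarray:
        """Scaled coordinate of a *difference* vector (affine offset cancels)."""
        d = self.initiation_direction
        return np.asarray(dpos) @ d / (d @ d)

    def selection_delta(self, dpos: np.ndarray) -> np.ndarray:
        e = self.selection_direction
        return 2.0 * (np.asarray(dpos) @ e) / (e @ e)


@dataclass
class Trajectory:
    """A condition-mean path through the model space around one event."""

    event: str
    times: np.ndarray              # relative grid, seconds
    positions: np.ndarray          # (T, K)
    n_trials: int
    initiation: np.ndarray | None = None  # scaled coordinates per time point
    selection: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def distance_travelled(self, axis: str = "initiation") -> np.ndarray:
        """Axis coordinate minus its value at the alignment event (t = 0)."""
        coord = getattr(self, axis)
        if coord is None:
            raise ValueError(f"axis coordinates not set for {axis!r}")
        i0 = int(np.argmin(np.abs(self.times)))
        return coord - coord[i0]


def build_population_matrix(avg_contra: np.ndarray, avg_ipsi: np.ndarray,
                            times: np.ndarray, unit_ids: np.ndarray | None = None,
                            ) -> PopulationMatrix:
    """Assemble and column-center R from per-unit condition averages.

    ``avg_contra``/``avg_ipsi`` are (N, T) condition-averaged Z rates around
    Center Out.  Units with non-finite averages in either condition are
    dropped with a log entry.
    """
    avg_contra = np.asarray(avg_contra, dtype=float)
    avg_ipsi = np.asarray(avg_ipsi, dtype=float)
    if avg_contra.shape != avg_ipsi.shape:
        raise ValueError("contra/ipsi averages must have matching shapes")
    n_units = avg_contra.shape[0]
    if unit_ids is None:
        unit_ids = np.arange(n_units)
    good = np.isfinite(avg_contra).all(axis=1) & np.isfinite(avg_ipsi).all(axis=1)
    if not good.all():
        log.info("build_population_matrix: dropped %d units with missing averages",
                 int((~good).sum()))
    if not good.any():
        raise ValueError("no units with complete condition averages")
    raw = np.concatenate([avg_contra[good].T, avg_ipsi[good].T], axis=0)  # (2T, N)
    col_means = raw.mean(axis=0)
    return PopulationMatrix(R=raw - col_means, column_means=col_means,
                            times=np.asarray(times, dtype=float),
                            conditions=("contra", "ipsi"),
                            unit_ids=np.asarray(unit_ids)[good])


def fit_pca(pm: PopulationMatrix, k: int = 10) -> StateSpaceModel:
    """SVD-based PCA of the centered population matrix.

    Keeps the first ``k`` right singular vectors (truncated with a warning if
    ``k`` exceeds the matrix rank).  Each component's sign is fixed so its
    largest-magnitude unit weight is positive (the SVD sign is arbitrary;
    axis definitions are sign-invariant, but stored scores must be
    deterministic).
    """
    R = pm.R
    _, svals, Vt = np.linalg.svd(R, full_matrices=False)
    tol = svals.max(initial=0.0) * max(R.shape) * np.finfo(float).eps
    rank = int((svals > tol).sum())
    if k > rank:
        log.warning("fit_pca: k=%d exceeds rank %d; truncating", k, rank)
        k = rank
    W = Vt[:k].T.copy()
    flips = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(k)])
    flips[flips == 0] = 1.0
    W *= flips
    var = svals ** 2 / (svals ** 2).sum()
    return StateSpaceModel(W=W, S=R @ W, variance_explained=var[:k],
                           column_means=pm.column_means, unit_ids=pm.unit_ids,
                           space="pc", sign_flips=flips)


def full_space_model(pm: PopulationMatrix) -> StateSpaceModel:
    """Identity-weight model: axes will live in the full N-D rate space."""
    n = pm.n_units
    W = np.eye(n)
    var = (pm.R ** 2).sum(axis=0)
    tot = var.sum()
    return StateSpaceModel(W=W, S=pm.R.copy(),
                           variance_explained=var / tot if tot > 0 else var,
                           column_means=pm.column_means, unit_ids=pm.unit_ids,
                           space="full")


def define_axes(go_positions: np.ndarray, centerout_positions: np.ndarray,
                contra_traj: np.ndarray, ipsi_traj: np.ndarray,
                space: str = "pc") -> AxisSet:
    """Anchor the two axes from positions already in the model space.

    ``go_positions``/``centerout_positions`` are (M, K) stacks of per-
    direction mean positions at the Go cue and at Center Out (averaged over
    rows); ``contra_traj``/``ipsi_traj`` are (T, K) movement-aligned mean
    trajectories whose full-window means anchor the Selection Axis.
    """
    a0 = np.atleast_2d(np.asarray(go_positions, dtype=float)).mean(axis=0)
    a1 = np.atleast_2d(np.asarray(centerout_positions, dtype=float)).mean(axis=0)
    m_c = np.asarray(contra_traj, dtype=float).mean(axis=0)
    m_i = np.asarray(ipsi_traj, dtype=float).mean(axis=0)
    return AxisSet(a0=a0, a1=a1, m_contra=m_c, m_ipsi=m_i, space=space)


def project_alignment(tensor: AlignedTensor, model: StateSpaceModel,
                      trial_mask: np.ndarray | None = None,
                      axes: AxisSet | None = None) -> Trajectory:
    """Project a condition-mean of aligned activity into the model space.

    The per-time-point population position is ``(mean_z - column_means) W``;
    when an :class:`AxisSet` is supplied the scaled axis coordinates are
    attached.  The tensor's unit set must match the model's.
    """
    if tensor.n_units != model.unit_ids.size or not np.array_equal(
            np.asarray(tensor.unit_ids), np.asarray(model.unit_ids)):
        raise ValueError("tensor and model unit sets differ")
    avg = condition_average(tensor, trial_mask)        # (N, T)
    pos = model.project(avg.T)                         # (T, K)
    n_tr = tensor.n_trials if trial_mask is None else int(
        np.count_nonzero(trial_mask) if np.asarray(trial_mask).dtype == bool
        else len(trial_mask))
    traj = Trajectory(event=tensor.event, times=tensor.times, positions=pos, n_trials=n_tr)
    if axes is not None:
        traj.initiation = axes.initiation_coord(pos)
        traj.selection = axes.selection_coord(pos)
    return traj


def axes_from_tensors(model: StateSpaceModel, center_out: AlignedTensor,
                      go_cue: AlignedTensor, contra_mask: np.ndarray,
                      ipsi_mask: np.ndarray, go_contra_mask: np.ndarray,
                      go_ipsi_mask: np.ndarray) -> AxisSet:
    """Derive the axis anchors from movement- and cue-aligned tensors.

    The Center-Out anchor and trajectory means come from the movement-
    aligned tensor (same trial set that built R); the Go-cue anchor is the
    t = 0 position of the Go-cue-aligned averages, averaged over the two
    movement directions.
    """
    traj_c = project_alignment(center_out, model, contra_mask)
    traj_i = project_alignment(center_out, model, ipsi_mask)
    i_co = int(np.argmin(np.abs(center_out.times)))
    a1 = np.stack([traj_c.positions[i_co], traj_i.positions[i_co]])

    go_c = project_alignment(go_cue, model, go_contra_mask)
    go_i = project_alignment(go_cue, model, go_ipsi_mask)
    i_go = int(np.argmin(np.abs(go_cue.times)))
    a0 = np.stack([go_c.positions[i_go], go_i.positions[i_go]])

    return define_axes(a0, a1, traj_c.positions, traj_i.positions, space=model.space)
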