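"""Trial-label permutation tests for state-space separation.

To decide whether the population occupies different state-space locations in
two trial conditions, trial labels are shuffled independently for each
neuron (preserving per-condition trial counts) and the between-condition
state-space difference is reconstructed from the shuffled condition-mean
firing-rate differences through the model weights:

    dx(t, k) = sum_n [ r(t, c1, n) - r(t, c2, n) ] * w(n, k)

The observed separation is compared to the surrogate distribution at each
time point (4 ms cadence) or on a window-averaged epoch.  The Euclidean
10-D distance is tested one-tailed; signed axis coordinates are tested
two-tailed about the center of the permutation distribution.

P-values use the permutation-inclusive ("add one") estimator
``p = (1 + #more-extreme-surrogates) / (1 + n_shuffles)``, which never
returns 0 and is exactly uniform under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .rates import AlignedTensor
from .statespace import AxisSet, StateSpaceModel

__all__ = [
    "PermutationSpec",
    "PermutationResult",
    "shuffle_conditions",
    "surrogate_statistic",
    "pointwise_pvalues",
    "epoch_test",
    "run_state_separation_tests",
]

STATISTICS = ("euclidean_10d", "initiation_coord", "selection_coord")

_UNIT_CHUNK = 16  # units processed per BLAS batch when reconstructing dx


@dataclass(frozen=True)
class PermutationSpec:
    """Configuration of one permutation test."""

    n_shuffles: int = 10000
    statistic: str = "euclidean_10d"
    tail: str | None = None        # "one" | "two"; default by statistic
    alpha: float = 0.05
    cadence: float = 0.004         # statistic time step, anchored at t = 0
    seed: int = 0
    window: tuple[float, float] | None = None  # set for epoch tests

    def __post_init__(self) -> None:
        if self.n_shuffles < 100:
            raise ValueError("n_shuffles must be >= 100")
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.tail not in (None, "one", "two"):
            raise ValueError("tail must be 'one' or 'two'")

    @property
    def effective_tail(self) -> str:
        if self.tail is not None:
            return self.tail
        return "one" if self.statistic == "euclidean_10d" else "two"


@dataclass
class PermutationResult:
    """Observed statistic, surrogate summary, and per-bin/epoch p-values."""

    statistic: str
    tail: str
    times: np.ndarray              # statistic time points (length 1 for epochs)
    observed: np.ndarray
    p: np.ndarray
    significant: np.ndarray        # p < alpha
    epochs: list[tuple[float, float]]  # maximal significant runs
    surrogate_mean: np.ndarray
    surrogate_lo: np.ndarray       # extreme-5% band edges of the null
    surrogate_hi: np.ndarray
    n_shuffles: int
    alpha: float
    seed: int
    spec: PermutationSpec | None = None
    meta: dict = field(default_factory=dict)

    @property
    def scalar_p(self) -> float:
        """Convenience for epoch (single-time-point) tests."""
        return float(self.p[0])

    @property
    def scalar_observed(self) -> float:
        return float(self.observed[0])

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "tail": self.tail,
            "times": self.times.tolist(),
            "observed": self.observed.tolist(),
            "p": self.p.tolist(),
            "significant": self.significant.tolist(),
            "epochs": [list(e) for e in self.epochs],
            "n_shuffles": self.n_shuffles,
            "alpha": self.alpha,
            "seed": self.seed,
        }


def shuffle_conditions(labels: np.ndarray, n_shuffles: int,
                       seed: int | np.random.SeedSequence,
                       n_units: int = 1) -> np.ndarray:
    """Per-unit random reassignments of trial conditions.

    ``labels`` is the (m,) boolean c1 membership shared by all units.
    Returns a (n_units, n_shuffles, m) boolean array; every surrogate
    partition preserves the per-condition trial counts, and each unit is
    shuffled independently.
    """
    labels = np.asarray(labels, dtype=bool)
    m = labels.size
    m1 = int(labels.sum())
    if m1 == 0 or m1 == m:
        raise ValueError("each condition needs at least one trial")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = np.zeros((n_units, n_shuffles, m), dtype=bool)
    for u, child in enumerate(ss.spawn(n_units)):
        out[u] = _unit_partitions(m, m1, n_shuffles, np.random.default_rng(child))
    return out


def _unit_partitions(m: int, m1: int, n_shuffles: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Count-preserving random c1 membership, (n_shuffles, m) boolean."""
    order = np.argsort(rng.random((n_shuffles, m)), axis=1)
    out = np.zeros((n_shuffles, m), dtype=bool)
    rows = np.repeat(np.arange(n_shuffles), m1)
    out[rows, order[:, :m1].ravel()] = True
    return out


def _cadence_indices(times: np.ndarray, step: float, cadence: float) -> np.ndarray:
    """Time-sample indices at the statistic cadence, anchored at t = 0."""
    per = max(1, int(round(cadence / step)))
    i0 = int(np.argmin(np.abs(times)))
    idx = np.arange(i0 % per, times.size, per)
    return idx


def _mean_diffs(values_u: np.ndarray, partitions_u: np.ndarray,
                labels: np.ndarray) -> np.ndarray:
    """Shuffled condition-mean differences for one unit: (S, T)."""
    m1 = int(labels.sum())
    m2 = labels.size - m1
    colsum = values_u.sum(axis=0)                      # (T,)
    B = partitions_u.astype(np.float32)                # (S, m)
    M = B @ values_u                                   # (S, T) sum over c1*
    return M * (1.0 / m1 + 1.0 / m2) - colsum / m2


def _delta_projections(values: np.ndarray, labels: np.ndarray,
                       W: np.ndarray, n_shuffles: int,
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Observed and surrogate dx(t, k) via the weight-projection formula.

    ``values`` is (N, m, T) aligned Z rates; returns
    ``(dx_obs (T, K), dx_surr (S, T, K))``.  One shuffle set is generated
    per unit and reused across time points, preserving the temporal
    smoothness of each surrogate trajectory.
    """
    values = np.asarray(values, dtype=np.float32)
    labels = np.asarray(labels, dtype=bool)
    n_units, m, n_time = values.shape
    W = np.asarray(W, dtype=np.float32)
    if W.shape[0] != n_units:
        raise ValueError("weight matrix does not match the tensor's unit set")

    dr_obs = values[:, labels].mean(axis=1) - values[:, ~labels].mean(axis=1)  # (N, T)
    dx_obs = dr_obs.T.astype(float) @ W.astype(float)                          # (T, K)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_units)
    m1 = int(labels.sum())
    dx_surr = np.zeros((n_shuffles, n_time, W.shape[1]), dtype=np.float64)
    for start in range(0, n_units, _UNIT_CHUNK):
        stop = min(start + _UNIT_CHUNK, n_units)
        D = np.empty((n_shuffles, n_time, stop - start), dtype=np.float32)
        for j, u in enumerate(range(start, stop)):
            parts = _unit_partitions(m, m1, n_shuffles, np.random.default_rng(children[u]))
            D[:, :, j] = _mean_diffs(values[u], parts, labels)
        dx_surr += D.astype(np.float64) @ W[start:stop].astype(np.float64)
    return dx_obs, dx_surr


def _extract_statistic(dx: np.ndarray, spec: PermutationSpec,
                       axes: AxisSet | None) -> np.ndarray:
    """Reduce dx(..., K) to the scalar separation statistic."""
    if spec.statistic == "euclidean_10d":
        return np.sqrt((dx ** 2).sum(axis=-1))
    if axes is None:
        raise ValueError("axis statistics require an AxisSet")
    if spec.statistic == "initiation_coord":
        return axes.initiation_delta(dx)
    return axes.selection_delta(dx)


def pointwise_pvalues(observed: np.ndarray, surrogates: np.ndarray,
                      spec: PermutationSpec, times: np.ndarray | None = None
                      ) -> PermutationResult:
    """Add-one permutation p-values per time point, with significance epochs.

    One-tailed: fraction of surrogates >= observed.  Two-tailed: both tails
    about the center of the pooled (surrogates + observed) distribution, so
    the estimator stays exactly exchangeable under the null.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    surrogates = np.asarray(surrogates, dtype=float)
    n_sh = surrogates.shape[0]
    if times is None:
        times = np.arange(observed.size, dtype=float)
    tail = spec.effective_tail
    if tail == "one":
        more = (surrogates >= observed[None, :]).sum(axis=0)
        lo = np.full(observed.size, -np.inf)
        hi = np.quantile(surrogates, 1.0 - spec.alpha, axis=0)
    else:
        center = (surrogates.sum(axis=0) + observed) / (n_sh + 1)
        more = (np.abs(surrogates - center) >= np.abs(observed - center)[None, :]).sum(axis=0)
        lo = np.quantile(surrogates, spec.alpha / 2, axis=0)
        hi = np.quantile(surrogates, 1.0 - spec.alpha / 2, axis=0)
    p = (1.0 + more) / (1.0 + n_sh)
    sig = p < spec.alpha
    epochs = _significant_epochs(times, sig)
    return PermutationResult(
        statistic=spec.statistic, tail=tail, times=np.asarray(times, dtype=float),
        observed=observed, p=p, significant=sig, epochs=epochs,
        surrogate_mean=surrogates.mean(axis=0), surrogate_lo=lo, surrogate_hi=hi,
        n_shuffles=n_sh, alpha=spec.alpha, seed=spec.seed, spec=spec)


def _significant_epochs(times: np.ndarray, sig: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of consecutive significant time points."""
    epochs = []
    in_run = False
    start = 0.0
    for t, s in zip(times, sig):
        if s and not in_run:
            in_run, start = True, float(t)
        elif not s and in_run:
            in_run = False
            epochs.append((start, float(prev)))
        prev = t
    if in_run:
        epochs.append((start, float(times[-1])))
    return epochs


def surrogate_statistic(tensor: AlignedTensor, labels: np.ndarray,
                        model: StateSpaceModel, spec: PermutationSpec,
                        axes: AxisSet | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed and surrogate separation statistics per time point.

    Returns ``(times, observed (T',), surrogates (S, T'))`` at the
    statistic cadence.
    """
    idx = _cadence_indices(tensor.times, tensor.step, spec.cadence)
    values = tensor.values[:, :, idx]
    dx_obs, dx_surr = _delta_projections(values, labels, model.W,
                                         spec.n_shuffles, spec.seed)
    return (tensor.times[idx],
            _extract_statistic(dx_obs, spec, axes),
            _extract_statistic(dx_surr, spec, axes))


def run_state_separation_tests(tensor: AlignedTensor, labels: np.ndarray,
                               model: StateSpaceModel, axes: AxisSet,
                               spec: PermutationSpec,
                               statistics: tuple[str, ...] = STATISTICS,
                               ) -> dict[str, PermutationResult]:
    """Pointwise tests for several statistics sharing one shuffle set.

    The expensive surrogate reconstruction dx(t, k) is computed once; the
    Euclidean and axis statistics are all derived from it, exactly as the
    observed statistics are derived from the observed condition difference.
    """
    idx = _cadence_indices(tensor.times, tensor.step, spec.cadence)
    values = tensor.values[:, :, idx]
    times = tensor.times[idx]
    dx_obs, dx_surr = _delta_projections(values, labels, model.W,
                                         spec.n_shuffles, spec.seed)
    out = {}
    for stat in statistics:
        s = replace(spec, statistic=stat)
        obs = _extract_statistic(dx_obs, s, axes)
        surr = _extract_statistic(dx_surr, s, axes)
        out[stat] = pointwise_pvalues(obs, surr, s, times=times)
    return out


def epoch_test(tensor: AlignedTensor, labels: np.ndarray,
               model: StateSpaceModel, window: tuple[float, float],
               spec: PermutationSpec, axes: AxisSet | None = None,
               statistics: tuple[str, ...] | None = None,
               ) -> dict[str, PermutationResult]:
    """Permutation test on the window-averaged state-space position.

    The aligned activity is averaged over the closed ``window`` (e.g. the
    100 ms before the Go cue), reducing the test to a single "time point";
    the same shuffle machinery and add-one p-value rule apply.  Returns one
    result per requested statistic (default: the spec's statistic).
    """
    sl = tensor.window_slice(window)
    values = tensor.values[:, :, sl].mean(axis=2, keepdims=True)
    dx_obs, dx_surr = _delta_projections(values, labels, model.W,
                                         spec.n_shuffles, spec.seed)
    stats_ = statistics or (spec.statistic,)
    t_mid = np.array([0.5 * (window[0] + window[1])])
    out = {}
    for stat in stats_:
        s = replace(spec, statistic=stat, window=tuple(window))
        obs = _extract_statistic(dx_obs, s, axes)
        surr = _extract_statistic(dx_surr, s, axes)
        res = pointwise_pvalues(obs, surr, s, times=t_mid)
        res.meta["window"] = tuple(window)
        out[stat] = res
    return out
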