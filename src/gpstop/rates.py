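"""Spike-train smoothing, session Z-scoring, event alignment, single-cell stats.

Smoothed firing rates are the sum of unit-mass Gaussian kernels (30 ms SD by
default) centred on each spike, evaluated on a regular grid (2 ms step) whose
sample times are integer multiples of the step.  Each unit is normalized to a
Z score using its own session-wide mean and SD, so 0 is "this unit's typical
rate" and deflections are in units of session SD.

Event alignment extracts per-trial snippets of the Z-scored rate on a closed
relative window: a 500 ms window at 2 ms step yields 251 samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "KernelConfig",
    "NeuronRates",
    "AlignedTensor",
    "DegenerateUnitError",
    "smooth_and_zscore",
    "align",
    "align_units",
    "compute_aligned_tensors",
    "condition_average",
    "direction_selectivity_by_bin",
    "peak_deflection",
    "compare_peak_deflections",
]

log = logging.getLogger("gpstop")


class DegenerateUnitError(ValueError):
    """Unit has no spikes (or zero rate variance) and cannot be Z-scored."""


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian smoothing kernel and sampling grid."""

    sd: float = 0.030            # kernel SD, seconds
    sample_step: float = 0.002   # grid step, seconds
    truncate_sd: float = 5.0     # kernel support, in SDs

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.sample_step <= 0 or self.truncate_sd <= 0:
            raise ValueError("kernel sd, sample_step and truncate_sd must be > 0")


@dataclass
class NeuronRates:
    """One unit's smoothed and Z-scored rate on the session grid.

    Sample ``j`` is at time ``(start_index + j) * step`` on the session clock.
    """

    unit_id: int
    start_index: int
    step: float
    rate: np.ndarray          # spikes/s
    z: np.ndarray             # (rate - session_mean) / session_sd
    session_mean: float
    session_sd: float

    @property
    def times(self) -> np.ndarray:
        return (self.start_index + np.arange(self.rate.size)) * self.step


@dataclass
class AlignedTensor:
    """Event-aligned snippets of Z-scored rate, axes (unit, trial, time)."""

    values: np.ndarray        # float32 (n_units, n_trials, n_time)
    times: np.ndarray         # relative time grid, seconds
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    event: str = ""
    step: float = 0.002
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_time(self) -> int:
        return self.values.shape[2]

    def select_trials(self, mask: np.ndarray) -> "AlignedTensor":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AlignedTensor(values=self.values[:, idx, :], times=self.times,
                             unit_ids=self.unit_ids, trial_ids=self.trial_ids[idx],
                             event=self.event, step=self.step, meta=dict(self.meta))

    def time_index(self, t: float) -> int:
        i = int(round((t - self.times[0]) / self.step))
        if not (0 <= i < self.n_time) or abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"time {t} not on the aligned grid")
        return i

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Indices of the closed window [w0, w1] on the relative grid."""
        i0 = int(math.ceil(round((window[0] - self.times[0]) / self.step, 9)))
        i1 = int(math.floor(round((window[1] - self.times[0]) / self.step, 9)))
        if i0 < 0 or i1 >= self.n_time or i1 < i0:
            raise ValueError(f"window {window} outside aligned range")
        return slice(i0, i1 + 1)


def smooth_and_zscore(spike_times: np.ndarray, span: tuple[float, float],
                      cfg: KernelConfig = KernelConfig(), unit_id: int = 0) -> NeuronRates:
    """Kernel-smooth one spike train and Z-score it session-wide.

    ``rate(t) = sum_spikes N(t - t_spike; sd)`` in spikes/s (each kernel
    integrates to 1).  Rates are computed on a grid padded by
    ``truncate_sd * sd`` beyond the span and then cropped, so spikes near the
    span edges keep their full kernel mass and no edge renormalization is
    needed.  Z-scoring uses the session-wide mean and population-formula SD.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        raise DegenerateUnitError(f"unit {unit_id}: no spikes in span")
    if spike_times.min() < span[0] - 1e-9 or spike_times.max() > span[1] + 1e-9:
        raise ValueError(f"unit {unit_id}: spikes outside span")

    step = cfg.sample_step
    i0 = int(math.ceil(round(span[0] / step, 9)))
    i1 = int(math.floor(round(span[1] / step, 9)))
    pad = int(math.ceil(cfg.truncate_sd * cfg.sd / step))
    n_padded = (i1 - i0 + 1) + 2 * pad

    # first-order (linear) deposition of each spike onto the padded grid
    x = spike_times / step - (i0 - pad)
    j = np.floor(x).astype(np.int64)
    w = x - j
    counts = np.bincount(j, weights=1.0 - w, minlength=n_padded + 1)
    counts += np.bincount(j + 1, weights=w, minlength=n_padded + 1)
    counts = counts[:n_padded]

    rate = gaussian_filter1d(counts, sigma=cfg.sd / step, mode="constant",
                             truncate=cfg.truncate_sd) / step
    rate = rate[pad: pad + (i1 - i0 + 1)]

    mean = float(rate.mean())
    sd = float(rate.std())  # population formula (ddof=0)
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateUnitError(f"unit {unit_id}: zero rate variance")
    z = (rate - mean) / sd
    return NeuronRates(unit_id=unit_id, start_index=i0, step=step,
                       rate=rate, z=z, session_mean=mean, session_sd=sd)


def _window_grid(window: tuple[float, float], step: float) -> tuple[int, np.ndarray]:
    n = int(round((window[1] - window[0]) / step)) + 1
    times = window[0] + np.arange(n) * step
    return n, times


def align(nr: NeuronRates, event_times: np.ndarray, window: tuple[float, float]
          ) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-event snippets of the Z-scored rate.

    Returns ``(snippets, valid)`` where ``snippets`` is (n_events, n_time)
    and ``valid`` marks events whose window lies fully inside the session
    span (others are NaN rows and flagged False).
    """
    event_times = np.asarray(event_times, dtype=float)
    n_time, _ = _window_grid(window, nr.step)
    out = np.full((event_times.size, n_time), np.nan)
    valid = np.zeros(event_times.size, dtype=bool)
    for k, e in enumerate(event_times):
        if not np.isfinite(e):
            continue
        j0 = int(round((e + window[0]) / nr.step)) - nr.start_index
        if j0 < 0 or j0 + n_time > nr.z.size:
            continue
        out[k] = nr.z[j0: j0 + n_time]
        valid[k] = True
    return out, valid


def align_units(neurons: list[NeuronRates], event_times: np.ndarray,
                window: tuple[float, float], trial_ids: np.ndarray | None = None,
                event: str = "") -> AlignedTensor:
    """Stack event-aligned snippets across units into an AlignedTensor.

    Events whose window exits the session (for any unit) are dropped with a
    log entry; an error is raised if none remain.
    """
    event_times = np.asarray(event_times, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(event_times.size)
    step = neurons[0].step
    n_time, times = _window_grid(window, step)
    snippets = []
    valid_all = np.ones(event_times.size, dtype=bool)
    for nr in neurons:
        snip, valid = align(nr, event_times, window)
        snippets.append(snip)
        valid_all &= valid
    n_dropped = int((~valid_all).sum())
    if n_dropped:
        log.info("align_units[%s]: dropped %d events with out-of-span windows", event, n_dropped)
    if not valid_all.any():
        raise ValueError(f"align_units[{event}]: no valid events")
    values = np.stack([s[valid_all] for s in snippets]).astype(np.float32)
    return AlignedTensor(values=values, times=times,
                         unit_ids=np.array([nr.unit_id for nr in neurons]),
                         trial_ids=np.asarray(trial_ids)[valid_all],
                         event=event, step=step)


def compute_aligned_tensors(spikes: dict[int, np.ndarray], span: tuple[float, float],
                            alignments: dict[str, tuple[np.ndarray, np.ndarray]],
                            window: tuple[float, float] = (-0.25, 0.25),
                            cfg: KernelConfig = KernelConfig(),
                            ) -> tuple[dict[str, AlignedTensor], dict]:
    """Smooth, Z-score and align every unit, streaming one unit at a time.

    ``alignments`` maps an alignment name to ``(event_times, trial_ids)``
    (NaN event times are skipped).  Full-session traces are discarded after
    alignment, so memory stays proportional to the aligned windows.  Units
    that cannot be Z-scored are dropped with a log entry.  Returns the
    tensors plus per-unit session statistics (mean/SD rate) and the dropped
    unit list.
    """
    step = cfg.sample_step
    n_time, times = _window_grid(window, step)
    unit_ids, dropped = [], []
    stats_rows = {"unit_id": [], "session_mean": [], "session_sd": []}
    # per alignment: keep finite events whose windows fit; validity is
    # determined once since all units share the session grid
    snip_store: dict[str, list[np.ndarray]] = {name: [] for name in alignments}
    valid_store: dict[str, np.ndarray] = {}

    for uid in sorted(spikes):
        try:
            nr = smooth_and_zscore(spikes[uid], span, cfg, unit_id=uid)
        except DegenerateUnitError as err:
            log.info("compute_aligned_tensors: dropping unit %s (%s)", uid, err)
            dropped.append(uid)
            continue
        unit_ids.append(uid)
        stats_rows["unit_id"].append(uid)
        stats_rows["session_mean"].append(nr.session_mean)
        stats_rows["session_sd"].append(nr.session_sd)
        for name, (etimes, _) in alignments.items():
            snip, valid = align(nr, np.asarray(etimes, dtype=float), window)
            if name not in valid_store:
                valid_store[name] = valid
            snip_store[name].append(snip[valid_store[name]].astype(np.float32))

    if not unit_ids:
        raise DegenerateUnitError("no units survived Z-scoring")
    tensors = {}
    for name, (etimes, tids) in alignments.items():
        valid = valid_store[name]
        n_dropped = int(np.isfinite(np.asarray(etimes, dtype=float)).sum() - valid.sum())
        if n_dropped:
            log.info("alignment %s: dropped %d events", name, n_dropped)
        tensors[name] = AlignedTensor(
            values=np.stack(snip_store[name]), times=times,
            unit_ids=np.asarray(unit_ids), trial_ids=np.asarray(tids)[valid],
            event=name, step=step)
    return tensors, {"unit_stats": stats_rows, "dropped_units": dropped}


def condition_average(tensor: AlignedTensor, trial_mask: np.ndarray | None = None) -> np.ndarray:
    """Pointwise mean over trials, per unit: (n_units, n_time)."""
    t = tensor if trial_mask is None else tensor.select_trials(trial_mask)
    if t.n_trials == 0:
        raise ValueError("condition_average: empty trial set")
    return t.values.mean(axis=1).astype(float)


@dataclass
class SelectivityResult:
    """Per-bin direction selectivity across the population."""

    bin_centers: np.ndarray
    pvalues: np.ndarray           # (n_units, n_bins)
    sign: np.ndarray              # +1 where contra > ipsi
    frac_significant: np.ndarray  # fraction of units with p < alpha per bin
    frac_contra: np.ndarray
    frac_ipsi: np.ndarray
    threshold_uncorrected: float  # binomial critical fraction, p<alpha
    threshold_corrected: float    # Bonferroni over bins
    alpha: float
    n_units: int


def _binom_critical_fraction(n: int, alpha: float, test_alpha: float) -> float:
    """Smallest fraction k/n with P(Binomial(n, alpha) >= k) < test_alpha."""
    k = np.arange(n + 2)
    sf = stats.binom.sf(k - 1, n, alpha)  # P(X >= k)
    return float(k[np.argmax(sf < test_alpha)]) / n


def direction_selectivity_by_bin(tensor_contra: AlignedTensor, tensor_ipsi: AlignedTensor,
                                 bin_width: float = 0.050, alpha: float = 0.05,
                                 min_trials: int = 2) -> SelectivityResult:
    """Per-unit, per-50 ms-bin two-sample t-tests of direction selectivity.

    For each unit and bin, trial-mean Z rates for contra vs ipsi trials are
    compared with an unpaired t-test.  The per-bin fraction of significant
    units is compared to the binomial critical fraction (chance level
    ``alpha``), with and without Bonferroni correction over bins.
    """
    if tensor_contra.n_trials < min_trials or tensor_ipsi.n_trials < min_trials:
        raise ValueError("need >= %d trials per side" % min_trials)
    step = tensor_contra.step
    per_bin = max(1, int(round(bin_width / step)))
    n_bins = tensor_contra.n_time // per_bin
    used = n_bins * per_bin

    def binned(t: AlignedTensor) -> np.ndarray:
        v = t.values[:, :, :used].reshape(t.n_units, t.n_trials, n_bins, per_bin)
        return v.mean(axis=3)  # (units, trials, bins)

    bc, bi = binned(tensor_contra), binned(tensor_ipsi)
    tstat, pval = stats.ttest_ind(bc, bi, axis=1)  # over trials
    sign = np.sign(bc.mean(axis=1) - bi.mean(axis=1))
    sig = pval < alpha
    n_units = tensor_contra.n_units
    frac = sig.mean(axis=0)
    frac_contra = (sig & (sign > 0)).mean(axis=0)
    frac_ipsi = (sig & (sign < 0)).mean(axis=0)
    centers = tensor_contra.times[:used].reshape(n_bins, per_bin).mean(axis=1)
    return SelectivityResult(
        bin_centers=centers, pvalues=pval, sign=sign, frac_significant=frac,
        frac_contra=frac_contra, frac_ipsi=frac_ipsi,
        threshold_uncorrected=_binom_critical_fraction(n_units, alpha, alpha),
        threshold_corrected=_binom_critical_fraction(n_units, alpha, alpha / n_bins),
        alpha=alpha, n_units=n_units)


def peak_deflection(avg: np.ndarray, times: np.ndarray,
                    window: tuple[float, float] = (-0.25, 0.25)
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximum |Z| deviation from the session mean within a window.

    ``avg`` is (n_time,) or (n_units, n_time).  Returns (magnitude, sign,
    time of the peak), each scalar or per-unit.
    """
    avg = np.atleast_2d(np.asarray(avg, dtype=float))
    m = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    if not m.any():
        raise ValueError("window outside the series")
    seg = avg[:, m]
    idx = np.argmax(np.abs(seg), axis=1)
    rows = np.arange(seg.shape[0])
    peaks = np.abs(seg[rows, idx])
    signs = np.sign(seg[rows, idx])
    ptimes = times[m][idx]
    if avg.shape[0] == 1:
        return peaks[0], signs[0], ptimes[0]
    return peaks, signs, ptimes


def compare_peak_deflections(peaks_a: np.ndarray, peaks_b: np.ndarray) -> tuple[float, float]:
    """Paired population comparison of peak deflections across alignments.

    Wilcoxon signed-rank over units; returns (statistic, p)."""
    res = stats.wilcoxon(np.asarray(peaks_a), np.asarray(peaks_b))
    return float(res.statistic), float(res.pvalue)
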