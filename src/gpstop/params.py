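"""Parameter containers for the synthetic stop-signal session generator.

Three parameter groups mirror the three ingredients of a session:

* :class:`TaskParams` — the timing rules of the behavioral task (hold delays,
  cue durations, stop-signal delays, response deadlines, block structure).
* :class:`RaceParams` — the independent-race model of going and stopping:
  finishing-time distributions for the Go and Stop processes, per start-port
  condition and movement direction.
* :class:`PopulationParams` — the recorded-population surrogate: tonic
  baseline rates, signed loadings of each unit on the two behavioral latents
  (initiation and selection), planted pre-Go state offsets per condition, and
  the rate-noise scale.

All durations are seconds on a double-precision session clock starting at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CONDITIONS",
    "DIRECTIONS",
    "ShiftedLogNormal",
    "TaskParams",
    "RaceParams",
    "PopulationParams",
    "load_params",
    "save_params",
]

#: Start-port conditions: which direction (if any) may be followed by a Stop cue.
CONDITIONS = ("maybe_stop_contra", "maybe_stop_ipsi", "no_stop")

#: Movement directions relative to the recorded hemisphere.
DIRECTIONS = ("contra", "ipsi")


class ParamError(ValueError):
    """Raised for infeasible or inconsistent generator parameters."""


@dataclass(frozen=True)
class ShiftedLogNormal:
    """Shifted log-normal finishing-time distribution.

    ``T = shift + scale * exp(sigma * Z)`` with ``Z`` standard normal.
    Positive support and right skew match empirical reaction-time
    distributions; the closed-form median ``shift + scale`` makes
    calibration to printed medians exact.
    """

    shift: float
    scale: float
    sigma: float

    def __post_init__(self) -> None:
        if self.shift < 0 or self.scale <= 0 or self.sigma <= 0:
            raise ParamError(f"invalid shifted log-normal: {self}")

    @property
    def median(self) -> float:
        return self.shift + self.scale

    @classmethod
    def from_median(cls, median: float, shift: float = 0.100, sigma: float = 0.6) -> "ShiftedLogNormal":
        """Calibrate the scale so the distribution's median equals ``median``."""
        if median <= shift:
            raise ParamError(f"median {median} must exceed shift {shift}")
        return cls(shift=shift, scale=median - shift, sigma=sigma)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return self.shift + self.scale * np.exp(self.sigma * rng.standard_normal(size))


def _check_range(name: str, lo: float, hi: float, positive: bool = True) -> None:
    if hi < lo or (positive and lo <= 0):
        raise ParamError(f"{name}: invalid range ({lo}, {hi})")


@dataclass(frozen=True)
class TaskParams:
    """Timing rules of the stop-signal task."""

    hold_delay_range: tuple[float, float] = (0.500, 1.250)
    go_cue_duration: float = 0.050
    stop_cue_duration: float = 0.125
    ssd_range: tuple[float, float] = (0.100, 0.250)
    rt_limit: float = 0.800
    mt_limit: float = 0.500
    stop_prob_on_maybe_cue: float = 0.5
    block_length_range: tuple[int, int] = (10, 15)
    iti_range: tuple[float, float] = (5.0, 7.0)
    n_go_trials: int = 266
    n_stop_trials: int = 57

    def __post_init__(self) -> None:
        _check_range("hold_delay_range", *self.hold_delay_range)
        _check_range("ssd_range", *self.ssd_range)
        _check_range("iti_range", *self.iti_range)
        if self.block_length_range[0] < 1 or self.block_length_range[1] < self.block_length_range[0]:
            raise ParamError("block_length_range must be increasing and >= 1")
        for name in ("go_cue_duration", "stop_cue_duration", "rt_limit", "mt_limit"):
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be > 0")
        if self.ssd_range[1] >= self.rt_limit:
            raise ParamError("ssd_range upper bound must be below rt_limit")
        if not 0.0 <= self.stop_prob_on_maybe_cue <= 1.0:
            raise ParamError("stop_prob_on_maybe_cue must be in [0, 1]")
        if self.n_go_trials < 0 or self.n_stop_trials < 0:
            raise ParamError("trial counts must be non-negative")

    @property
    def n_trials(self) -> int:
        """Total trials generated per session (Go + Stop targets)."""
        return self.n_go_trials + self.n_stop_trials


def _default_go_dists() -> dict[tuple[str, str], ShiftedLogNormal]:
    # Calibration anchors: observed correct-contra median RT of 0.251 s with
    # no Stop cue possible, 0.385 s when a contra Stop cue could occur, and
    # 0.264 s for the unslowed direction within a Maybe-Stop context
    # (symmetric for the Maybe-Stop-ipsi context).  The slowed latent median
    # is set above its observed target because correct trials censor the
    # finishing-time distribution at the 0.8 s RT limit and Stop-scheduled
    # trials with very fast Go finishes re-enter the Go pool: a latent
    # median of 0.416 s yields an observed correct-trial median of 0.385 s
    # under the default task timing.
    slow = ShiftedLogNormal.from_median(0.416)
    base = ShiftedLogNormal.from_median(0.251)
    off = ShiftedLogNormal.from_median(0.264)
    return {
        ("no_stop", "contra"): base,
        ("no_stop", "ipsi"): base,
        ("maybe_stop_contra", "contra"): slow,
        ("maybe_stop_contra", "ipsi"): off,
        ("maybe_stop_ipsi", "ipsi"): slow,
        ("maybe_stop_ipsi", "contra"): off,
    }


def _default_wrong_choice() -> dict[tuple[str, str], float]:
    # Incorrect action selection is more common when the cued direction might
    # have to be cancelled (preparatory bias toward the alternative action).
    probs = {}
    for cond in CONDITIONS:
        for d in DIRECTIONS:
            maybe_dir = cond == f"maybe_stop_{d}"
            probs[(cond, d)] = 0.10 if maybe_dir else 0.02
    return probs


@dataclass(frozen=True)
class RaceParams:
    """Independent-race model of action initiation and stopping.

    ``go_finish_dists`` maps (condition, go direction) to the finishing-time
    distribution of the Go process (measured from Go-cue onset); the slowing
    of Maybe-Stop-direction movements lives in these per-condition scales.
    ``stop_finish_dist`` is the Stop process finishing time measured from
    Stop-cue onset.  ``proactive_rt_shift`` is an optional extra additive
    slowing of Maybe-Stop-direction Go finishing times (seconds; default 0 —
    the calibrated per-condition medians already carry the slowing).
    """

    go_finish_dists: dict[tuple[str, str], ShiftedLogNormal] = field(default_factory=_default_go_dists)
    stop_finish_dist: ShiftedLogNormal = ShiftedLogNormal(shift=0.030, scale=0.160, sigma=0.4)
    proactive_rt_shift: float = 0.0
    movement_time_dist: ShiftedLogNormal = ShiftedLogNormal(shift=0.050, scale=0.200, sigma=0.25)
    wrong_choice_prob: dict[tuple[str, str], float] = field(default_factory=_default_wrong_choice)
    hold_lapse_prob: float = 0.0  # post-success hold failures (late failed-stop tail); off by default

    def __post_init__(self) -> None:
        for key in [(c, d) for c in CONDITIONS for d in DIRECTIONS]:
            if key not in self.go_finish_dists:
                raise ParamError(f"go_finish_dists missing entry for {key}")
        for p in self.wrong_choice_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ParamError("wrong_choice_prob entries must be in [0, 1]")
        if not 0.0 <= self.hold_lapse_prob <= 1.0:
            raise ParamError("hold_lapse_prob must be in [0, 1]")
        if self.proactive_rt_shift < 0:
            raise ParamError("proactive_rt_shift must be >= 0")

    def go_finish(self, condition: str, direction: str, rng: np.random.Generator) -> float:
        t = float(self.go_finish_dists[(condition, direction)].sample(rng))
        if self.proactive_rt_shift and condition == f"maybe_stop_{direction}":
            t += self.proactive_rt_shift
        return t


def _default_offsets() -> dict[str, tuple[float, float]]:
    # (initiation, selection) offsets in latent units: the full Go-cue ->
    # Center-Out excursion is 1 on the initiation latent and the contra/ipsi
    # endpoints are +1/-1 on the selection latent.  Under proactive
    # inhibition the population starts farther from initiation and biased
    # toward the alternative action.
    return {
        "no_stop": (0.0, 0.0),
        "maybe_stop_contra": (-0.4, -0.5),
        "maybe_stop_ipsi": (-0.4, +0.5),
    }


@dataclass(frozen=True)
class PopulationParams:
    """Latent-factor Poisson surrogate for the recorded population.

    Each unit fires as an inhomogeneous Poisson process with rate

    ``max(0, baseline + w_init * L_I(t) + w_sel * L_S(t) + trial noise)``

    where ``L_I`` rises from the per-condition pre-Go offset toward 1 at
    movement onset and ``L_S`` moves toward +1 (contra) or -1 (ipsi).
    Loadings are signed (mixed rate increases and decreases, as observed in
    pallidal recordings).
    """

    n_neurons: int = 376
    baseline_rate_mean: float = 28.0   # across-unit mean tonic rate, spikes/s
    baseline_rate_shape: float = 4.0   # gamma shape of the tonic-rate distribution
    init_loading_sd: float = 5.0       # spikes/s per unit of the initiation latent
    sel_loading_sd: float = 5.0        # spikes/s per unit of the selection latent
    pre_go_state_offsets: dict[str, tuple[float, float]] = field(default_factory=_default_offsets)
    noise_sd: float = 2.0              # per-trial, per-unit rate jitter, spikes/s
    offset_ramp: float = 0.100         # s, onset ramp of the pre-Go offset after Center In
    release_tau: float = 0.200         # s, latent decay after movement completion
    abort_tau: float = 0.150           # s, latent decay after a successful stop

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ParamError("n_neurons must be >= 1")
        for name in ("baseline_rate_mean", "baseline_rate_shape", "offset_ramp", "release_tau", "abort_tau"):
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be > 0")
        for name in ("init_loading_sd", "sel_loading_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be >= 0")
        for cond in CONDITIONS:
            if cond not in self.pre_go_state_offsets:
                raise ParamError(f"pre_go_state_offsets missing condition {cond}")


# ---------------------------------------------------------------------------
# (De)serialization — YAML/JSON round trip for configs.

def _encode(obj):
    if isinstance(obj, ShiftedLogNormal):
        return {"shift": obj.shift, "scale": obj.scale, "sigma": obj.sigma}
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else "|".join(k)): _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def params_to_dict(task: TaskParams, race: RaceParams, pop: PopulationParams) -> dict:
    return {
        "task": _encode(asdict(task)),
        "race": _encode(asdict(race)),
        "population": _encode(asdict(pop)),
    }


def _decode_dist(d) -> ShiftedLogNormal:
    return ShiftedLogNormal(**d)


def params_from_dict(cfg: dict) -> tuple[TaskParams, RaceParams, PopulationParams]:
    t = dict(cfg.get("task", {}))
    for key in ("hold_delay_range", "ssd_range", "iti_range", "block_length_range"):
        if key in t:
            t[key] = tuple(t[key])
    task = TaskParams(**t)

    r = dict(cfg.get("race", {}))
    for key in ("go_finish_dists", "wrong_choice_prob"):
        if key in r:
            r[key] = {tuple(k.split("|")): (_decode_dist(v) if key == "go_finish_dists" else v)
                      for k, v in r[key].items()}
    for key in ("stop_finish_dist", "movement_time_dist"):
        if key in r:
            r[key] = _decode_dist(r[key])
    race = RaceParams(**r)

    p = dict(cfg.get("population", {}))
    if "pre_go_state_offsets" in p:
        p["pre_go_state_offsets"] = {k: tuple(v) for k, v in p["pre_go_state_offsets"].items()}
    pop = PopulationParams(**p)
    return task, race, pop


def save_params(path: str | Path, task: TaskParams, race: RaceParams, pop: PopulationParams) -> None:
    path = Path(path)
    cfg = params_to_dict(task, race, pop)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))


def load_params(path: str | Path) -> tuple[TaskParams, RaceParams, PopulationParams]:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return params_from_dict(cfg)
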