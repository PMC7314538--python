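"""Synthetic stop-signal sessions: race-model behavior + latent-factor spiking.

A session is generated in two stages.

``generate_behavior`` draws trials organised in start-port blocks.  Each
trial races an underlying Go process (finishing time measured from Go-cue
onset, per condition and direction) against a Stop process (measured from
Stop-cue onset) on Stop-scheduled trials.  If the Go process finishes before
the Stop cue would appear, the trial is emitted as a plain Go trial (the
Stop cue is never presented).  Otherwise the earlier finisher determines a
failed (movement) or successful (hold) stop.

``generate_spikes`` turns the trials into inhomogeneous-Poisson spike trains.
Every unit's rate is ``max(0, baseline + w_init * L_I(t) + w_sel * L_S(t) +
trial noise)``, where the initiation latent ``L_I`` sits at the planted
per-condition pre-Go offset during the hold, ramps to 1 at movement onset at
the trial's own Go-process speed, and relaxes back to baseline after the
movement (or after the Stop process wins); the selection latent ``L_S``
ramps toward +1 for contra and -1 for ipsi choices.  The planted offsets and
loadings are returned as ground truth so downstream recovery can be scored
without re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import TrialRecord
from .params import CONDITIONS, DIRECTIONS, PopulationParams, RaceParams, TaskParams

__all__ = ["GroundTruth", "SyntheticSession", "generate_behavior", "generate_spikes", "generate_session"]

_SESSION_START = 1.0     # s of quiet baseline before the first trial
_SESSION_PAD = 1.0       # s of quiet baseline after the last trial
_POST_TRIAL = 0.5        # s from last movement event to nominal trial end


@dataclass
class GroundTruth:
    """Latent state of a synthetic session, sufficient to score recovery.

    Per-trial arrays are index-aligned with the emitted trial list; times are
    on the session clock.  ``go_finish``/``stop_finish`` are the sampled race
    finishing times (stop_finish is NaN when no Stop process ran);
    ``move_onset``/``move_end`` are the true movement times even when the
    emitted record censors them (RT-limit errors); ``halt_time`` is when the
    Stop process froze the Go process on successful stops.
    """

    go_finish: np.ndarray
    stop_finish: np.ndarray
    scheduled_stop: np.ndarray
    converted: np.ndarray
    choice_sign: np.ndarray          # +1 contra, -1 ipsi, 0 no movement started
    move_onset: np.ndarray
    move_end: np.ndarray
    halt_time: np.ndarray
    trial_start: np.ndarray
    trial_end: np.ndarray
    pre_go_state_offsets: dict[str, tuple[float, float]]
    baseline_rates: np.ndarray | None = None
    init_loadings: np.ndarray | None = None
    sel_loadings: np.ndarray | None = None

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return {
            "go_finish": arr(self.go_finish),
            "stop_finish": arr(self.stop_finish),
            "scheduled_stop": arr(self.scheduled_stop),
            "converted": arr(self.converted),
            "choice_sign": arr(self.choice_sign),
            "move_onset": arr(self.move_onset),
            "move_end": arr(self.move_end),
            "halt_time": arr(self.halt_time),
            "trial_start": arr(self.trial_start),
            "trial_end": arr(self.trial_end),
            "pre_go_state_offsets": {k: list(v) for k, v in self.pre_go_state_offsets.items()},
            "baseline_rates": arr(self.baseline_rates),
            "init_loadings": arr(self.init_loadings),
            "sel_loadings": arr(self.sel_loadings),
        }


@dataclass
class SyntheticSession:
    """A complete synthetic session: trials, spikes, span, and ground truth."""

    trials: list[TrialRecord]
    ground_truth: GroundTruth
    spikes: dict[int, np.ndarray] = field(default_factory=dict)
    span: tuple[float, float] = (0.0, 0.0)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _block_conditions(task: TaskParams, rng: np.random.Generator) -> list[str]:
    """Condition label per trial: start-port blocks of 10-15 trials, the three
    contexts visited in shuffled order within each round."""
    labels: list[str] = []
    while len(labels) < task.n_trials:
        conds = list(CONDITIONS)
        rng.shuffle(conds)
        for c in conds:
            n = int(rng.integers(task.block_length_range[0], task.block_length_range[1] + 1))
            labels.extend([c] * n)
    return labels[: task.n_trials]


def generate_behavior(task: TaskParams, race: RaceParams,
                      seed: int | np.random.Generator) -> tuple[list[TrialRecord], GroundTruth]:
    """Simulate one session of race-model behavior.

    Outcome labels are left unset (``behavior.classify_trials`` assigns
    them); Stop trials are rewarded iff the hold was maintained for the full
    RT-limit period after Go-cue onset.
    """
    rng = _rng(seed)
    conditions = _block_conditions(task, rng)
    n = len(conditions)

    trials: list[TrialRecord] = []
    go_finish = np.empty(n)
    stop_finish = np.full(n, np.nan)
    scheduled = np.zeros(n, dtype=bool)
    converted = np.zeros(n, dtype=bool)
    choice_sign = np.zeros(n)
    move_onset = np.full(n, np.nan)
    move_end = np.full(n, np.nan)
    halt_time = np.full(n, np.nan)
    t_start = np.empty(n)
    t_end = np.empty(n)

    t = _SESSION_START
    for i, cond in enumerate(conditions):
        t_center_in = t
        hold = rng.uniform(*task.hold_delay_range)
        t_go = t_center_in + hold
        direction = DIRECTIONS[int(rng.integers(2))]
        goT = race.go_finish(cond, direction, rng)
        wrong = rng.random() < race.wrong_choice_prob[(cond, direction)]
        choice = (DIRECTIONS[1 - DIRECTIONS.index(direction)] if wrong else direction)
        sign = +1.0 if choice == "contra" else -1.0
        mt = float(race.movement_time_dist.sample(rng))

        is_scheduled = (cond == f"maybe_stop_{direction}"
                        and rng.random() < task.stop_prob_on_maybe_cue)
        ssd = float(rng.uniform(*task.ssd_range)) if is_scheduled else None
        scheduled[i] = is_scheduled
        go_finish[i] = goT

        delivered_ssd: float | None = None
        t_center_out: float | None = None
        t_side_in: float | None = None
        rewarded = False

        if is_scheduled and goT <= ssd:
            # movement began before the Stop cue: converted into a Go trial
            converted[i] = True
            is_scheduled = False
            ssd = None

        if is_scheduled:
            stopT = float(race.stop_finish_dist.sample(rng))
            stop_finish[i] = stopT
            delivered_ssd = ssd
            if goT < ssd + stopT and goT < task.rt_limit:
                # Go process wins the race: failed stop
                t_center_out = t_go + goT
                t_side_in = t_center_out + mt
                choice_sign[i] = sign
                move_onset[i] = t_center_out
                move_end[i] = t_side_in
            else:
                # Stop process wins (or the hold requirement elapsed first):
                # hold maintained through the limited hold
                halt_time[i] = t_go + min(ssd + stopT, task.rt_limit)
                if race.hold_lapse_prob and rng.random() < race.hold_lapse_prob:
                    # late hold failure: exits after stopping, before reward
                    t_center_out = t_go + rng.uniform(0.5, task.rt_limit - 1e-6)
                    t_side_in = t_center_out + mt
                    choice_sign[i] = sign
                    move_onset[i] = t_center_out
                    move_end[i] = t_side_in
                else:
                    rewarded = True
        else:
            # plain Go trial (including converted Stop trials)
            t_center_out_true = t_go + goT
            t_side_in_true = t_center_out_true + mt
            choice_sign[i] = sign
            move_onset[i] = t_center_out_true
            move_end[i] = t_side_in_true
            if goT <= task.rt_limit:
                t_center_out = t_center_out_true
                t_side_in = t_side_in_true
                rewarded = (choice == direction) and (mt <= task.mt_limit)
            # else: RT-limit error — the eventual exit is censored from the
            # emitted record (the trial had already timed out)

        last = np.nanmax([move_end[i], halt_time[i], t_go + task.rt_limit])
        t_start[i] = t_center_in
        t_end[i] = last + _POST_TRIAL
        trials.append(TrialRecord(
            trial_id=i, condition=cond, go_direction=direction,
            t_center_in=t_center_in, t_go=t_go, ssd=delivered_ssd,
            t_center_out=t_center_out, t_side_in=t_side_in,
            choice=(choice if t_center_out is not None else None),
            rewarded=rewarded,
        ))
        t = t_end[i] + rng.uniform(*task.iti_range)

    gt = GroundTruth(
        go_finish=go_finish, stop_finish=stop_finish, scheduled_stop=scheduled,
        converted=converted, choice_sign=choice_sign, move_onset=move_onset,
        move_end=move_end, halt_time=halt_time, trial_start=t_start, trial_end=t_end,
        pre_go_state_offsets={},
    )
    return trials, gt


def latent_timecourses(trials: list[TrialRecord], gt: GroundTruth,
                       pop: PopulationParams, tgrid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the initiation and selection latents on a time grid.

    Returns ``(L_I, L_S)`` arrays over ``tgrid``.  Both are 0 between
    trials; during the hold they sit at the per-condition planted offsets
    (ramped on over ``pop.offset_ramp``); after the Go cue they move toward
    their movement targets at the trial's Go-process speed and relax
    exponentially after movement completion or a successful stop.
    """
    LI = np.zeros_like(tgrid)
    LS = np.zeros_like(tgrid)
    for i, tr in enumerate(trials):
        oI, oS = pop.pre_go_state_offsets[tr.condition]
        i0 = int(np.searchsorted(tgrid, gt.trial_start[i]))
        stop_t = gt.trial_end[i] + 5.0 * pop.release_tau
        if i + 1 < len(trials):
            stop_t = min(stop_t, gt.trial_start[i + 1])
        i1 = int(np.searchsorted(tgrid, stop_t))
        if i1 <= i0:
            continue
        t = tgrid[i0:i1]
        ramp_on = np.clip((t - tr.t_center_in) / pop.offset_ramp, 0.0, 1.0)
        li = oI * ramp_on
        ls = oS * ramp_on

        goT = gt.go_finish[i]
        sign = gt.choice_sign[i]
        after_go = t >= tr.t_go
        rho = np.clip((t - tr.t_go) / goT, 0.0, 1.0)
        li_go = oI + (1.0 - oI) * rho
        ls_go = oS + (sign - oS) * rho
        li = np.where(after_go, li_go, li)
        ls = np.where(after_go, ls_go, ls)

        if np.isfinite(gt.halt_time[i]) and not np.isfinite(gt.move_onset[i]):
            # successful stop: progress frozen at the halt, then released
            th = gt.halt_time[i]
            rho_h = np.clip((th - tr.t_go) / goT, 0.0, 1.0)
            li_h = oI + (1.0 - oI) * rho_h
            ls_h = oS + (sign - oS) * rho_h
            decay = np.exp(-(t - th) / pop.abort_tau)
            halted = t >= th
            li = np.where(halted, li_h * decay, li)
            ls = np.where(halted, ls_h * decay, ls)
        elif np.isfinite(gt.move_end[i]):
            # movement completed: latents held at target during the movement
            # (rho clips at 1), then relax after Side In
            te = gt.move_end[i]
            decay = np.exp(-(t - te) / pop.release_tau)
            done = t >= te
            li = np.where(done, 1.0 * decay, li)
            ls = np.where(done, sign * decay, ls)
        LI[i0:i1] = li
        LS[i0:i1] = ls
    return LI, LS


def generate_spikes(trials: list[TrialRecord], gt: GroundTruth, pop: PopulationParams,
                    seed: int | np.random.Generator,
                    sample_step: float = 0.002,
                    baseline_rates: np.ndarray | None = None,
                    init_loadings: np.ndarray | None = None,
                    sel_loadings: np.ndarray | None = None,
                    ) -> tuple[dict[int, np.ndarray], tuple[float, float]]:
    """Inhomogeneous-Poisson spike trains for every unit, plus the session span.

    Rates are evaluated on a ``sample_step`` grid (piecewise-constant
    intensity), spike counts drawn per bin and jittered uniformly within the
    bin.  Spiking continues at baseline through inter-trial intervals.
    Loadings and baselines may be supplied explicitly (arrays of length
    ``pop.n_neurons``); otherwise they are drawn from the population
    distributions and recorded in the ground truth.
    """
    rng = _rng(seed)
    n_units = pop.n_neurons
    span = (0.0, float(np.max(gt.trial_end)) + _SESSION_PAD)
    tgrid = np.arange(0.0, span[1], sample_step)
    LI, LS = latent_timecourses(trials, gt, pop, tgrid)

    if baseline_rates is None:
        baseline_rates = rng.gamma(pop.baseline_rate_shape,
                                   pop.baseline_rate_mean / pop.baseline_rate_shape,
                                   size=n_units)
    if init_loadings is None:
        init_loadings = rng.normal(0.0, pop.init_loading_sd, size=n_units)
    if sel_loadings is None:
        sel_loadings = rng.normal(0.0, pop.sel_loading_sd, size=n_units)
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    init_loadings = np.asarray(init_loadings, dtype=float)
    sel_loadings = np.asarray(sel_loadings, dtype=float)
    gt.baseline_rates = baseline_rates
    gt.init_loadings = init_loadings
    gt.sel_loadings = sel_loadings

    # map each grid sample to its trial (or -1 between trials) for trial noise
    trial_of_bin = np.full(tgrid.size, -1, dtype=np.int64)
    for i in range(len(trials)):
        a = int(np.searchsorted(tgrid, gt.trial_start[i]))
        b = int(np.searchsorted(tgrid, gt.trial_end[i]))
        trial_of_bin[a:b] = i

    spikes: dict[int, np.ndarray] = {}
    in_trial = trial_of_bin >= 0
    idx = np.where(in_trial, trial_of_bin, 0)
    for u in range(n_units):
        rate = baseline_rates[u] + init_loadings[u] * LI + sel_loadings[u] * LS
        if pop.noise_sd > 0:
            trial_noise = rng.normal(0.0, pop.noise_sd, size=len(trials))
            rate = rate + np.where(in_trial, trial_noise[idx], 0.0)
        np.clip(rate, 0.0, None, out=rate)
        counts = rng.poisson(rate * sample_step)
        nz = np.flatnonzero(counts)
        reps = counts[nz]
        times = np.repeat(tgrid[nz], reps) + rng.uniform(0.0, sample_step, size=int(reps.sum()))
        spikes[u] = np.sort(np.minimum(times, span[1]))
    return spikes, span


def generate_session(task: TaskParams | None = None,
                     race: RaceParams | None = None,
                     pop: PopulationParams | None = None,
                     seed: int | np.random.Generator = 0,
                     with_spikes: bool = True,
                     **spike_kwargs) -> SyntheticSession:
    """End-to-end convenience: behavior, then (optionally) spikes."""
    task = task or TaskParams()
    race = race or RaceParams()
    pop = pop or PopulationParams()
    rng = _rng(seed)
    trials, gt = generate_behavior(task, race, rng)
    gt.pre_go_state_offsets = dict(pop.pre_go_state_offsets)
    session = SyntheticSession(trials=trials, ground_truth=gt)
    if with_spikes:
        session.spikes, session.span = generate_spikes(trials, gt, pop, rng, **spike_kwargs)
    else:
        session.span = (0.0, float(np.max(gt.trial_end)) + _SESSION_PAD)
    return session
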