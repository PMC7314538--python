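"""End-to-end session analysis: from events + spikes to axis statistics.

``run_all`` runs the complete set of analyses on one session (synthetic
or user-supplied): behavioral summary and inclusion screen, single-cell
direction selectivity and peak deflections, the PCA state space with
Initiation/Selection axes, Stop-trial trajectory comparisons, pre-Go-cue
condition and error-type contrasts, correct-trial proactive contrasts with
RT median splits and RT matching, and a full-dimensional (no-PCA) replica
of the key tests.  Every reported p-value comes from a
:class:`~gpstop.permstats.PermutationResult`; runs are deterministic given
the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import behavior as bh
from . import io as gio
from . import permstats as ps
from . import rates as rt
from . import statespace as ss
from . import synth
from .params import PopulationParams, RaceParams, TaskParams, params_from_dict

__all__ = ["AnalysisConfig", "SessionData", "prepare_session",
           "run_go_stop_analysis", "run_proactive_analysis", "run_all"]

log = logging.getLogger("gpstop")

MIN_TRIALS_PER_CLASS = 10


@dataclass
class AnalysisConfig:
    """Everything a reproducible run needs; the seed is mandatory."""

    seed: int
    events_path: str | None = None
    spikes_path: str | None = None
    generator: dict = field(default_factory=dict)   # task/race/population overrides
    kernel_sd: float = 0.030
    sample_step: float = 0.002
    window: tuple[float, float] = (-0.25, 0.25)
    n_components: int = 10
    n_shuffles: int = 10000
    alpha: float = 0.05
    cadence: float = 0.004
    pre_go_window: tuple[float, float] = (-0.100, 0.0)
    singlecell_analysis: bool = True
    stop_analysis: bool = True
    pre_go_analysis: bool = True
    proactive_analysis: bool = True
    full_space_axes: bool = True
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        for key in ("window", "pre_go_window"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        d["pre_go_window"] = list(self.pre_go_window)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SessionData:
    """A classified session with aligned tensors and a fitted state space."""

    trials: list[bh.TrialRecord]
    df: pd.DataFrame                       # neural-analysis trial set, by trial_id
    behavior_summary: dict
    tensors: dict[str, rt.AlignedTensor]
    pm: ss.PopulationMatrix
    model: ss.StateSpaceModel
    axes: ss.AxisSet
    full_model: ss.StateSpaceModel | None = None
    full_axes: ss.AxisSet | None = None
    ground_truth: synth.GroundTruth | None = None
    dropped_units: list = field(default_factory=list)
    unit_stats: dict = field(default_factory=dict)   # session mean/SD rate per unit
    task: TaskParams | None = None


def _mask(df: pd.DataFrame, tensor: rt.AlignedTensor, **crit) -> np.ndarray:
    """Boolean mask over a tensor's trials from column criteria.

    Values may be scalars or lists; the special key ``stop_cue`` selects on
    Stop-cue delivery.
    """
    sub = df.loc[tensor.trial_ids]
    m = np.ones(len(sub), dtype=bool)
    for key, val in crit.items():
        if key == "stop_cue":
            col = sub["ssd"].notna().to_numpy()
            m &= col if val else ~col
            continue
        col = sub[key]
        m &= (col.isin(val) if isinstance(val, (list, tuple, set)) else (col == val)).to_numpy()
    return m


def prepare_session(config: AnalysisConfig) -> SessionData:
    """Load/generate, classify, smooth, align, and fit the state space."""
    rng = np.random.default_rng(config.seed)
    gt = None
    if config.events_path:
        trials = gio.read_events_csv(config.events_path)
        spikes = gio.read_spikes_csv(config.spikes_path)
        last = max(float(np.max(s)) for s in spikes.values() if len(s))
        span = (0.0, max(last, max(t.t_go for t in trials) + 2.0) + 0.5)
        task, _, _ = params_from_dict(config.generator) if config.generator else (TaskParams(), None, None)
    else:
        task, race, pop = (params_from_dict(config.generator) if config.generator
                           else (TaskParams(), RaceParams(), PopulationParams()))
        session = synth.generate_session(task, race, pop, seed=rng,
                                         sample_step=config.sample_step)
        trials, spikes, span, gt = session.trials, session.spikes, session.span, session.ground_truth

    trials = bh.classify_trials(trials, task)
    summary = bh.summarize_session(trials, alpha=config.alpha)
    neural = [t for t in trials if t.outcome != "aborted"]
    neural = bh.exclude_late_failed_stops(neural)
    df = bh.trials_to_frame(neural).set_index("trial_id", drop=False)

    ids = df.trial_id.to_numpy()
    t_go = df.t_go.to_numpy(dtype=float)
    t_co = df.t_center_out.to_numpy(dtype=float)
    t_stop = (df.t_go + df.ssd).to_numpy(dtype=float)
    alignments = {"go_cue": (t_go, ids), "center_out": (t_co, ids), "stop_cue": (t_stop, ids)}
    cfg = rt.KernelConfig(sd=config.kernel_sd, sample_step=config.sample_step)
    tensors, info = rt.compute_aligned_tensors(spikes, span, alignments,
                                               window=config.window, cfg=cfg)

    co = tensors["center_out"]
    m_contra = _mask(df, co, outcome="correct_go", condition="no_stop", go_direction="contra")
    m_ipsi = _mask(df, co, outcome="correct_go", condition="no_stop", go_direction="ipsi")
    if m_contra.sum() < 2 or m_ipsi.sum() < 2:
        raise ValueError("too few correct No-Stop trials to build the population matrix")
    avg_c = rt.condition_average(co, m_contra)
    avg_i = rt.condition_average(co, m_ipsi)
    pm = ss.build_population_matrix(avg_c, avg_i, co.times, unit_ids=co.unit_ids)
    model = ss.fit_pca(pm, k=config.n_components)

    go = tensors["go_cue"]
    g_contra = _mask(df, go, outcome="correct_go", condition="no_stop", go_direction="contra")
    g_ipsi = _mask(df, go, outcome="correct_go", condition="no_stop", go_direction="ipsi")
    axes = ss.axes_from_tensors(model, co, go, m_contra, m_ipsi, g_contra, g_ipsi)

    full_model = full_axes = None
    if config.full_space_axes:
        full_model = ss.full_space_model(pm)
        full_axes = ss.axes_from_tensors(full_model, co, go, m_contra, m_ipsi,
                                         g_contra, g_ipsi)
    return SessionData(trials=trials, df=df, behavior_summary=summary, tensors=tensors,
                       pm=pm, model=model, axes=axes, full_model=full_model,
                       full_axes=full_axes, ground_truth=gt,
                       dropped_units=info["dropped_units"],
                       unit_stats=info["unit_stats"], task=task)


def _result_block(results: dict[str, ps.PermutationResult]) -> dict:
    return {name: res.to_dict() for name, res in results.items()}


def _epoch_block(results: dict[str, ps.PermutationResult]) -> dict:
    return {name: {"observed": res.scalar_observed, "p": res.scalar_p,
                   "significant": bool(res.significant[0]), "tail": res.tail}
            for name, res in results.items()}


def run_singlecell_analysis(sd: SessionData, config: AnalysisConfig) -> dict:
    """Direction selectivity per 50 ms bin and peak-deflection comparisons."""
    co, go = sd.tensors["center_out"], sd.tensors["go_cue"]
    m_c = _mask(sd.df, co, outcome="correct_go", condition="no_stop", go_direction="contra")
    m_i = _mask(sd.df, co, outcome="correct_go", condition="no_stop", go_direction="ipsi")
    sel = rt.direction_selectivity_by_bin(co.select_trials(m_c), co.select_trials(m_i),
                                          alpha=config.alpha)
    avg_co = rt.condition_average(co, m_c)
    g_c = _mask(sd.df, go, outcome="correct_go", condition="no_stop", go_direction="contra")
    avg_go = rt.condition_average(go, g_c)
    pk_co, _, _ = rt.peak_deflection(avg_co, co.times)
    pk_go, _, _ = rt.peak_deflection(avg_go, go.times)
    w_stat, w_p = rt.compare_peak_deflections(pk_co, pk_go)
    return {
        "selectivity": {
            "bin_centers": sel.bin_centers.tolist(),
            "frac_significant": sel.frac_significant.tolist(),
            "frac_contra": sel.frac_contra.tolist(),
            "frac_ipsi": sel.frac_ipsi.tolist(),
            "threshold_uncorrected": sel.threshold_uncorrected,
            "threshold_corrected": sel.threshold_corrected,
        },
        "peak_deflection": {
            "median_center_out": float(np.median(pk_co)),
            "median_go_cue": float(np.median(pk_go)),
            "wilcoxon_p": w_p,
        },
    }


def run_go_stop_analysis(sd: SessionData, config: AnalysisConfig) -> dict:
    """Successful- vs Failed-Stop state-space comparison (reactive stopping).

    Stop-cue-aligned pointwise Euclidean tests plus epoch tests of the
    position at the Go cue and at the Stop cue, on all three statistics.
    """
    stop = sd.tensors["stop_cue"]
    failed = _mask(sd.df, stop, outcome="failed_stop")
    succ = _mask(sd.df, stop, outcome="successful_stop")
    if failed.sum() < MIN_TRIALS_PER_CLASS or succ.sum() < MIN_TRIALS_PER_CLASS:
        log.info("go_stop: skipped (failed=%d, successful=%d)", failed.sum(), succ.sum())
        return {"skipped": True, "n_failed": int(failed.sum()), "n_successful": int(succ.sum())}
    both = failed | succ
    sub = stop.select_trials(both)
    labels = failed[both]  # c1 = failed stops
    spec = ps.PermutationSpec(n_shuffles=config.n_shuffles, alpha=config.alpha,
                              cadence=config.cadence, seed=config.seed)
    pointwise = ps.run_state_separation_tests(sub, labels, sd.model, sd.axes, spec,
                                              statistics=("euclidean_10d", "initiation_coord"))
    at_stop = ps.epoch_test(sub, labels, sd.model, (0.0, 0.0), spec, sd.axes,
                            statistics=ps.STATISTICS)
    go = sd.tensors["go_cue"]
    g_failed = _mask(sd.df, go, outcome="failed_stop")
    g_succ = _mask(sd.df, go, outcome="successful_stop")
    g_both = g_failed | g_succ
    at_go = ps.epoch_test(go.select_trials(g_both), g_failed[g_both], sd.model,
                          (0.0, 0.0), spec, sd.axes, statistics=ps.STATISTICS)

    traj_failed = ss.project_alignment(sub, sd.model, labels, sd.axes)
    traj_succ = ss.project_alignment(sub, sd.model, ~labels, sd.axes)
    return {
        "skipped": False,
        "n_failed": int(failed.sum()), "n_successful": int(succ.sum()),
        "pointwise_stop_aligned": _result_block(pointwise),
        "epoch_at_stop_cue": _epoch_block(at_stop),
        "epoch_at_go_cue": _epoch_block(at_go),
        "initiation_at_stop_cue": {
            "failed": float(traj_failed.initiation[np.argmin(np.abs(traj_failed.times))]),
            "successful": float(traj_succ.initiation[np.argmin(np.abs(traj_succ.times))]),
        },
    }


def _contrast(sd: SessionData, tensor, m1, m2, spec, model=None, axes=None,
              window=(0.0, 0.0), min_n=MIN_TRIALS_PER_CLASS) -> dict | None:
    if m1.sum() < min_n or m2.sum() < min_n:
        return None
    both = m1 | m2
    res = ps.epoch_test(tensor.select_trials(both), m1[both],
                        model or sd.model, window, spec, axes or sd.axes,
                        statistics=ps.STATISTICS)
    out = _epoch_block(res)
    out["n_c1"], out["n_c2"] = int(m1.sum()), int(m2.sum())
    out["window"] = list(window)
    return out


def run_proactive_analysis(sd: SessionData, config: AnalysisConfig) -> dict:
    """Proactive-inhibition contrasts: pre-Go state, error types, correct trials."""
    go = sd.tensors["go_cue"]
    spec = ps.PermutationSpec(n_shuffles=config.n_shuffles, alpha=config.alpha,
                              cadence=config.cadence, seed=config.seed)
    out: dict = {}

    # Pre-Go-cue condition contrast: all Maybe-Stop-contra trial subtypes vs No-Stop
    m_maybe = _mask(sd.df, go, condition="maybe_stop_contra")
    m_no = _mask(sd.df, go, condition="no_stop")
    out["pre_go_condition"] = _contrast(sd, go, m_maybe, m_no, spec,
                                        window=config.pre_go_window)

    # Outcome breakdown at the Go cue: errors vs correct, contra cues under
    # proactive inhibition
    base = dict(condition="maybe_stop_contra", go_direction="contra", stop_cue=False)
    m_corr = _mask(sd.df, go, outcome="correct_go", **base)
    out["outcome_breakdown"] = {}
    for err in ("wrong_choice", "rt_limit_error"):
        m_err = _mask(sd.df, go, outcome=err, **base)
        res = _contrast(sd, go, m_err, m_corr, spec, window=config.pre_go_window, min_n=5)
        out["outcome_breakdown"][err] = res if res is not None else {"skipped": True}

    # Correct-trial proactive contrast (no Stop cues on either side)
    m_maybe_c = _mask(sd.df, go, outcome="correct_go", condition="maybe_stop_contra",
                      go_direction="contra", stop_cue=False)
    m_no_c = _mask(sd.df, go, outcome="correct_go", condition="no_stop",
                   go_direction="contra")
    out["correct_trials"] = _contrast(sd, go, m_maybe_c, m_no_c, spec, window=(0.0, 0.0))

    if out["correct_trials"] is not None:
        both = m_maybe_c | m_no_c
        t_my = ss.project_alignment(go, sd.model, m_maybe_c, sd.axes)
        t_no = ss.project_alignment(go, sd.model, m_no_c, sd.axes)
        out["distance_travelled"] = {
            "times": t_my.times.tolist(),
            "maybe_stop": {"initiation": t_my.distance_travelled("initiation").tolist(),
                           "selection": t_my.distance_travelled("selection").tolist()},
            "no_stop": {"initiation": t_no.distance_travelled("initiation").tolist(),
                        "selection": t_no.distance_travelled("selection").tolist()},
        }

    # RT median split within correct No-Stop contra trials
    rts = sd.df.loc[go.trial_ids[m_no_c]].rt.to_numpy(dtype=float)
    if rts.size >= 2 * MIN_TRIALS_PER_CLASS:
        fast, slow = bh.median_split(rts)
        idx_no = np.flatnonzero(m_no_c)
        m_fast = np.zeros(go.n_trials, dtype=bool)
        m_slow = np.zeros(go.n_trials, dtype=bool)
        m_fast[idx_no[fast]] = True
        m_slow[idx_no[slow]] = True
        out["median_split"] = _contrast(sd, go, m_slow, m_fast, spec, window=(0.0, 0.0))
    else:
        out["median_split"] = None

    # RT-matched control: Maybe-Stop vs No-Stop with equalized RTs
    rts_my = sd.df.loc[go.trial_ids[m_maybe_c]].rt.to_numpy(dtype=float)
    try:
        pairs = bh.rt_match_trials(rts_my, rts, seed=config.seed)
        idx_my = np.flatnonzero(m_maybe_c)
        idx_no = np.flatnonzero(m_no_c)
        mm = np.zeros(go.n_trials, dtype=bool)
        mn = np.zeros(go.n_trials, dtype=bool)
        mm[idx_my[[i for i, _ in pairs]]] = True
        mn[idx_no[[j for _, j in pairs]]] = True
        out["rt_matched"] = _contrast(sd, go, mm, mn, spec, window=(0.0, 0.0))
        if out["rt_matched"] is not None:
            out["rt_matched"]["n_pairs"] = len(pairs)
            out["rt_matched"]["median_rt_maybe"] = float(np.median(rts_my[[i for i, _ in pairs]]))
            out["rt_matched"]["median_rt_no"] = float(np.median(rts[[j for _, j in pairs]]))
    except bh.MatchingError as err:
        log.info("rt matching skipped: %s", err)
        out["rt_matched"] = {"skipped": True, "reason": str(err)}
    return out


def run_fullspace_analysis(sd: SessionData, config: AnalysisConfig) -> dict:
    """Key contrasts replicated with axes in the full N-D space (no PCA)."""
    go = sd.tensors["go_cue"]
    spec = ps.PermutationSpec(n_shuffles=config.n_shuffles, alpha=config.alpha,
                              cadence=config.cadence, seed=config.seed)
    m_maybe = _mask(sd.df, go, condition="maybe_stop_contra")
    m_no = _mask(sd.df, go, condition="no_stop")
    out = {"pre_go_condition": _contrast(sd, go, m_maybe, m_no, spec,
                                         model=sd.full_model, axes=sd.full_axes,
                                         window=config.pre_go_window)}
    return out


def run_all(config: AnalysisConfig) -> dict:
    """Run every enabled analysis; return (and optionally write) the report."""
    sd = prepare_session(config)
    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "seed": config.seed,
            "gpstop_version": _version,
            "dropped_units": list(sd.dropped_units),
        },
        "behavior": sd.behavior_summary,
        "state_space": {
            "n_units": int(sd.pm.n_units),
            "n_timepoints_per_condition": int(sd.pm.n_time),
            "variance_explained": sd.model.variance_explained.tolist(),
        },
    }
    if config.singlecell_analysis:
        report["singlecell"] = run_singlecell_analysis(sd, config)
    if config.stop_analysis:
        report["go_stop"] = run_go_stop_analysis(sd, config)
    if config.pre_go_analysis or config.proactive_analysis:
        report["proactive"] = run_proactive_analysis(sd, config)
    if config.full_space_axes:
        report["full_space"] = run_fullspace_analysis(sd, config)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        bh.trials_to_frame(sd.trials).to_csv(outdir / "trials.csv", index=False)
        gio.save_model(outdir / "model", sd.model, sd.axes)
    return report
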