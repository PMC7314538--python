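"""Trial records, outcome classification, and behavioral statistics.

The stop-signal task rules implemented here: after a variable hold in the
center port a Go cue instructs a leftward or rightward movement; leaving the
center port ("Center Out") must happen within the RT limit (0.8 s) and the
correct side port must be reached ("Side In") within the MT limit (0.5 s).
On Stop trials the Go cue is followed, after the stop-signal delay (SSD), by
a Stop cue; the trial is rewarded only if the nose is held in the center
port for a total of 0.8 s after Go-cue onset.

Outcome taxonomy (exhaustive and mutually exclusive over well-formed
trials): ``correct_go``, ``rt_limit_error``, ``mt_limit_error``,
``wrong_choice``, ``successful_stop``, ``failed_stop``; premature exits
before the Go cue are labelled ``aborted`` and excluded from all analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import TaskParams

__all__ = [
    "OUTCOMES",
    "TrialRecord",
    "MalformedTrialError",
    "classify_trial",
    "classify_trials",
    "exclude_late_failed_stops",
    "test_session_inclusion",
    "rt_match_trials",
    "median_split",
    "trials_to_frame",
    "summarize_session",
]

OUTCOMES = (
    "correct_go",
    "rt_limit_error",
    "mt_limit_error",
    "wrong_choice",
    "successful_stop",
    "failed_stop",
    "aborted",
)

#: Failed-Stop trials slower than this are presumed hold failures after a
#: successful reaction to the Stop cue, and are excluded from neural analyses.
LATE_FAILED_STOP_RT = 0.500


class MalformedTrialError(ValueError):
    """A trial is missing mandatory events or has inconsistent event order."""


class UndefinedTestError(ValueError):
    """A statistical test was requested on empty or insufficient samples."""


class MatchingError(ValueError):
    """RT matching produced too few or unbalanced pairs."""


@dataclass
class TrialRecord:
    """One trial's condition, events (session clock, seconds) and outcome.

    ``ssd`` is present iff a Stop cue was actually delivered; Stop-scheduled
    trials on which movement began before the Stop cue are emitted as plain
    Go trials.  ``choice`` is the side actually entered (None if the rat
    never left the center port).
    """

    trial_id: int
    condition: str            # maybe_stop_contra | maybe_stop_ipsi | no_stop
    go_direction: str         # contra | ipsi
    t_center_in: float
    t_go: float
    ssd: float | None = None
    t_center_out: float | None = None
    t_side_in: float | None = None
    choice: str | None = None
    rewarded: bool = False
    outcome: str | None = None

    @property
    def t_stop(self) -> float | None:
        """Stop-cue onset time, if a Stop cue was delivered."""
        return None if self.ssd is None else self.t_go + self.ssd

    @property
    def rt(self) -> float | None:
        """Reaction time: Go cue to Center Out."""
        return None if self.t_center_out is None else self.t_center_out - self.t_go

    @property
    def mt(self) -> float | None:
        """Movement time: Center Out to Side In."""
        if self.t_center_out is None or self.t_side_in is None:
            return None
        return self.t_side_in - self.t_center_out

    @property
    def is_stop_trial(self) -> bool:
        return self.ssd is not None


def classify_trial(trial: TrialRecord, task: TaskParams) -> str:
    """Label one trial's outcome under the task's timing rules."""
    if trial.t_go is None or trial.t_center_in is None:
        raise MalformedTrialError(f"trial {trial.trial_id}: missing mandatory events")
    if trial.t_go < trial.t_center_in:
        raise MalformedTrialError(f"trial {trial.trial_id}: Go cue precedes Center In")
    rt = trial.rt
    if rt is not None and rt < 0:
        return "aborted"  # premature Center Out, before the Go cue
    if trial.t_side_in is not None and trial.t_center_out is None:
        raise MalformedTrialError(f"trial {trial.trial_id}: Side In without Center Out")

    if trial.is_stop_trial:
        # Held through the limited-hold period => stop succeeded.
        if rt is None or rt >= task.rt_limit:
            return "successful_stop"
        return "failed_stop"

    if rt is None or rt > task.rt_limit:
        return "rt_limit_error"
    if trial.choice is not None and trial.choice != trial.go_direction:
        return "wrong_choice"
    mt = trial.mt
    if mt is None or mt > task.mt_limit:
        return "mt_limit_error"
    return "correct_go"


def classify_trials(trials: Iterable[TrialRecord], task: TaskParams) -> list[TrialRecord]:
    """Classify every trial, returning new records with ``outcome`` set."""
    return [replace(t, outcome=classify_trial(t, task)) for t in trials]


def exclude_late_failed_stops(trials: Sequence[TrialRecord],
                              rt_cutoff: float = LATE_FAILED_STOP_RT) -> list[TrialRecord]:
    """Drop Failed-Stop trials with RT above ``rt_cutoff`` (default 0.5 s).

    These are presumed hold failures rather than true failures to stop and
    are excluded from neural analyses (they remain in behavioral summaries).
    """
    return [t for t in trials
            if not (t.outcome == "failed_stop" and t.rt is not None and t.rt > rt_cutoff)]


def test_session_inclusion(maybe_stop_rts: Sequence[float],
                           no_stop_rts: Sequence[float],
                           alpha: float = 0.05) -> tuple[bool, float]:
    """Proactive-inhibition screen: one-tailed Wilcoxon rank-sum test.

    Tests whether Maybe-Stop RTs are longer than No-Stop RTs; a session is
    included when p < ``alpha``.  Uses the exact null when both samples have
    fewer than 20 observations (and no ties), the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(maybe_stop_rts, dtype=float)
    b = np.asarray(no_stop_rts, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedTestError("need >=2 RTs per condition for the inclusion test")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size < 20 and b.size < 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    p = float(res.pvalue)
    return p < alpha, p


def rt_match_trials(rts_a: Sequence[float], rts_b: Sequence[float],
                    seed: int | np.random.Generator | None = 0,
                    tolerance: float = 0.020,
                    min_pairs: int = 10,
                    balance_alpha: float = 0.2) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour RT matching without replacement.

    Repeatedly pairs the globally closest (a, b) RTs, discarding candidate
    pairs with |dRT| above ``tolerance`` (default 20 ms).  Raises
    :class:`MatchingError` if fewer than ``min_pairs`` survive or if the
    matched RT sets remain rank-sum distinguishable (p <= ``balance_alpha``).
    Returns (index_in_a, index_in_b) pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(rts_a, dtype=float)
    b = np.asarray(rts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MatchingError("empty RT set")
    diff = np.abs(a[:, None] - b[None, :])
    # tiny random tie-break keeps the greedy order deterministic per seed
    diff = diff + rng.uniform(0.0, 1e-12, size=diff.shape)
    pairs: list[tuple[int, int]] = []
    used_a = np.zeros(a.size, dtype=bool)
    used_b = np.zeros(b.size, dtype=bool)
    order = np.argsort(diff, axis=None)
    for flat in order:
        i, j = divmod(int(flat), b.size)
        if used_a[i] or used_b[j]:
            continue
        if abs(a[i] - b[j]) > tolerance:
            break  # all remaining candidates are at least this far apart
        pairs.append((i, j))
        used_a[i] = used_b[j] = True
    if len(pairs) < min_pairs:
        raise MatchingError(f"only {len(pairs)} RT-matched pairs (need >= {min_pairs})")
    ma = a[[i for i, _ in pairs]]
    mb = b[[j for _, j in pairs]]
    if not np.allclose(ma, mb):
        p = float(stats.mannwhitneyu(ma, mb, alternative="two-sided").pvalue)
        if p <= balance_alpha:
            raise MatchingError(f"matched RT sets remain distinguishable (rank-sum p={p:.3f})")
    return pairs


def median_split(rts: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Split trial indices at the sample median RT; ties go to the fast set."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        raise UndefinedTestError("median split needs >= 2 trials")
    med = float(np.median(rts))
    fast = np.flatnonzero(rts <= med)
    slow = np.flatnonzero(rts > med)
    return fast, slow


# ---------------------------------------------------------------------------
# Session-level summaries

def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy per-trial table with derived RT/MT and outcome labels."""
    rows = []
    for t in trials:
        rows.append({
            "trial_id": t.trial_id,
            "condition": t.condition,
            "go_direction": t.go_direction,
            "choice": t.choice,
            "t_center_in": t.t_center_in,
            "t_go": t.t_go,
            "ssd": t.ssd,
            "t_center_out": t.t_center_out,
            "t_side_in": t.t_side_in,
            "rewarded": t.rewarded,
            "rt": t.rt,
            "mt": t.mt,
            "outcome": t.outcome,
        })
    return pd.DataFrame(rows)


def summarize_session(trials: Sequence[TrialRecord], alpha: float = 0.05) -> dict:
    """Session-level behavioral summary.

    Per-condition correct-trial median RTs (split by direction), outcome
    proportions per condition, and the proactive-inhibition inclusion test
    comparing correct Maybe-Stop-contra vs No-Stop contra RTs.
    """
    df = trials_to_frame(trials)
    df = df[df.outcome != "aborted"]
    out: dict = {"n_trials": int(len(df)), "median_rt": {}, "outcome_proportions": {}, "counts": {}}
    for cond, g in df.groupby("condition"):
        props = g.outcome.value_counts(normalize=True).to_dict()
        out["outcome_proportions"][cond] = {k: float(v) for k, v in props.items()}
        out["counts"][cond] = {k: int(v) for k, v in g.outcome.value_counts().to_dict().items()}
        med = {}
        for d, gd in g[g.outcome == "correct_go"].groupby("go_direction"):
            med[d] = float(gd.rt.median())
        out["median_rt"][cond] = med

    maybe = df[(df.condition == "maybe_stop_contra") & (df.outcome == "correct_go")
               & (df.go_direction == "contra")].rt.dropna()
    nostop = df[(df.condition == "no_stop") & (df.outcome == "correct_go")
                & (df.go_direction == "contra")].rt.dropna()
    if len(maybe) >= 2 and len(nostop) >= 2:
        include, p = test_session_inclusion(maybe.to_numpy(), nostop.to_numpy(), alpha=alpha)
        out["inclusion"] = {"include": bool(include), "p": p}
    else:
        out["inclusion"] = {"include": False, "p": None}
    return out
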