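"""Race-model behavior generation and latent-factor spike synthesis."""

import collections

import numpy as np
import pytest
from scipy import stats

import gpstop as g
from gpstop.params import ParamError, ShiftedLogNormal, _default_go_dists
from gpstop.synth import generate_behavior, generate_spikes


def uniform_race(median=0.251):
    """Race params with identical Go distributions in every condition."""
    d = ShiftedLogNormal.from_median(median)
    return g.RaceParams(go_finish_dists={k: d for k in _default_go_dists()})


class TestParams:
    def test_infeasible_params_rejected(self):
        with pytest.raises(ParamError):
            g.TaskParams(ssd_range=(0.9, 1.0))  # SSD beyond the RT limit
        with pytest.raises(ParamError):
            g.TaskParams(hold_delay_range=(1.0, 0.5))
        with pytest.raises(ParamError):
            ShiftedLogNormal(shift=-0.1, scale=0.2, sigma=0.5)
        with pytest.raises(ParamError):
            g.PopulationParams(n_neurons=0)

    def test_closed_form_median(self):
        d = ShiftedLogNormal.from_median(0.385)
        assert d.median == pytest.approx(0.385)
        s = d.sample(np.random.default_rng(0), size=200_000)
        assert np.median(s) == pytest.approx(0.385, abs=0.002)
        assert (s > 0).all()

    def test_yaml_round_trip(self, tmp_path):
        task, race, pop = g.TaskParams(n_go_trials=50), g.RaceParams(), g.PopulationParams(n_neurons=5)
        g.save_params(tmp_path / "p.yml", task, race, pop)
        t2, r2, p2 = g.load_params(tmp_path / "p.yml")
        assert t2 == task and p2.n_neurons == 5
        assert r2.go_finish_dists == race.go_finish_dists


class TestBehaviorGeneration:
    def test_blocks_and_determinism(self):
        task = g.TaskParams(n_go_trials=80, n_stop_trials=20)
        t1, _ = generate_behavior(task, g.RaceParams(), 5)
        t2, _ = generate_behavior(task, g.RaceParams(), 5)
        assert [a.t_go for a in t1] == [b.t_go for b in t2]
        # condition runs respect the block-length bounds (except the cut tail)
        runs = [len(list(v)) for _, v in __import__("itertools").groupby(
            [t.condition for t in t1])]
        # adjacent rounds may repeat a condition, merging two blocks
        assert all(10 <= r <= 30 for r in runs[:-1])

    def test_fast_go_converts_stop_trials(self):
        """Go finishing before the SSD means the Stop cue is never shown."""
        fast = ShiftedLogNormal(shift=0.01, scale=0.04, sigma=0.3)  # median 50 ms < min SSD
        race = g.RaceParams(go_finish_dists={k: fast for k in _default_go_dists()})
        task = g.TaskParams(n_go_trials=60, n_stop_trials=40, stop_prob_on_maybe_cue=1.0)
        trials, gt = generate_behavior(task, race, 0)
        assert gt.scheduled_stop.sum() > 10
        assert all(t.ssd is None for t in trials)          # every Stop converted
        assert gt.converted.sum() == gt.scheduled_stop.sum()
        outcomes = collections.Counter(t.outcome for t in g.classify_trials(trials, task))
        assert "failed_stop" not in outcomes and "successful_stop" not in outcomes

    def test_all_slow_go_yields_only_rt_limit_errors(self):
        slow = ShiftedLogNormal(shift=1.5, scale=0.5, sigma=0.2)   # always > 0.8 s
        race = g.RaceParams(go_finish_dists={k: slow for k in _default_go_dists()},
                            wrong_choice_prob={k: 0.0 for k in _default_go_dists()})
        task = g.TaskParams(n_go_trials=40, n_stop_trials=0, stop_prob_on_maybe_cue=0.0)
        trials = g.classify_trials(generate_behavior(task, race, 1)[0], task)
        assert {t.outcome for t in trials} == {"rt_limit_error"}

    def test_calibrated_no_stop_median(self):
        """Large-n sample median matches the closed-form 251 ms target."""
        race = g.RaceParams()
        rng = np.random.default_rng(2)
        s = np.array([race.go_finish("no_stop", "contra", rng) for _ in range(10_000)])
        assert np.median(s) == pytest.approx(0.251, abs=0.006)

    def test_null_slowing_is_exchangeable(self):
        """With identical Go distributions, the inclusion screen rejects ~alpha."""
        task = g.TaskParams(n_go_trials=130, n_stop_trials=30)
        race = uniform_race()
        rejections = 0
        for seed in range(20):
            trials = g.classify_trials(generate_behavior(task, race, seed)[0], task)
            rejections += g.summarize_session(trials)["inclusion"]["include"]
        assert rejections <= 2  # non-significant in >=90% of null seeds

    def test_failed_stops_are_fast(self, task_defaults):
        """Race property: failed-stop RTs sit in the fast part of the Go RT mix."""
        race = g.RaceParams()
        failed, go = [], []
        for seed in range(6):
            trials = g.classify_trials(generate_behavior(task_defaults, race, seed)[0],
                                       task_defaults)
            failed += [t.rt for t in trials if t.outcome == "failed_stop"]
            go += [t.rt for t in trials
                   if t.outcome in ("correct_go", "wrong_choice", "mt_limit_error")
                   and t.condition == "maybe_stop_contra"
                   and t.go_direction == "contra" and t.rt is not None]
        assert len(failed) > 30
        p = stats.mannwhitneyu(failed, go, alternative="less").pvalue
        assert p < 1e-3
        assert np.median(failed) < np.median(go)


class TestSpikeGeneration:
    def test_homogeneous_poisson_count(self):
        """All loadings zero -> plain Poisson at the baseline rate."""
        task = g.TaskParams(n_go_trials=8, n_stop_trials=2, iti_range=(5.0, 7.0))
        trials, gt = generate_behavior(task, g.RaceParams(), 3)
        pop = g.PopulationParams(n_neurons=4, noise_sd=0.0, init_loading_sd=0.0,
                                 sel_loading_sd=0.0)
        spikes, span = generate_spikes(trials, gt, pop, 0,
                                       baseline_rates=np.full(4, 20.0),
                                       init_loadings=np.zeros(4), sel_loadings=np.zeros(4))
        dur = span[1] - span[0]
        for u in range(4):
            expected = 20.0 * dur
            assert abs(len(spikes[u]) - expected) < 5 * np.sqrt(expected)

    def test_mean_population_rate_near_28hz(self):
        """Across-neuron mean session-wide rate of a default-size population."""
        task = g.TaskParams(n_go_trials=35, n_stop_trials=8, iti_range=(1.0, 2.0))
        trials, gt = generate_behavior(task, g.RaceParams(), 4)
        pop = g.PopulationParams()  # 376 units, default rate distribution
        spikes, span = generate_spikes(trials, gt, pop, 4)
        dur = span[1] - span[0]
        rates = np.array([len(spikes[u]) / dur for u in spikes])
        assert rates.mean() == pytest.approx(28.0, abs=2.5)

    def test_opposite_selection_loadings_give_opposite_differences(self):
        task = g.TaskParams(n_go_trials=60, n_stop_trials=0, iti_range=(1.0, 2.0),
                            stop_prob_on_maybe_cue=0.0)
        trials, gt = generate_behavior(task, g.RaceParams(), 6)
        pop = g.PopulationParams(n_neurons=2, noise_sd=0.0)
        spikes, span = generate_spikes(trials, gt, pop, 1,
                                       baseline_rates=np.full(2, 30.0),
                                       init_loadings=np.zeros(2),
                                       sel_loadings=np.array([8.0, -8.0]))
        classified = g.classify_trials(trials, task)
        diffs = []
        for u in range(2):
            t = spikes[u]
            per_dir = {"contra": [], "ipsi": []}
            for tr in classified:
                if tr.outcome != "correct_go" or tr.t_center_out is None:
                    continue
                n = np.count_nonzero((t >= tr.t_center_out - 0.1) & (t <= tr.t_center_out + 0.2))
                per_dir[tr.go_direction].append(n)
            diffs.append(np.mean(per_dir["contra"]) - np.mean(per_dir["ipsi"]))
        assert diffs[0] > 0 > diffs[1]

    def test_ground_truth_records_race_and_loadings(self, small_session):
        gt = small_session.ground_truth
        n = len(small_session.trials)
        assert gt.go_finish.shape == (n,)
        assert np.isfinite(gt.go_finish).all() and (gt.go_finish > 0).all()
        assert gt.init_loadings.shape == (20,)
        # mixed signs: increases and decreases both present
        assert (gt.sel_loadings > 0).any() and (gt.sel_loadings < 0).any()
        # failed stops: go process beat the stop process
        for i, tr in enumerate(small_session.trials):
            if tr.ssd is not None and tr.t_center_out is not None:
                assert gt.go_finish[i] < tr.ssd + gt.stop_finish[i]
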