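"""Trial-label shuffling, surrogate projection, and permutation p-values."""

import numpy as np
import pytest

from gpstop.permstats import (PermutationSpec, epoch_test, pointwise_pvalues,
                              shuffle_conditions, surrogate_statistic)
from gpstop.rates import AlignedTensor
from gpstop.statespace import AxisSet, StateSpaceModel


def make_tensor(values, step=0.002):
    values = np.asarray(values, dtype=np.float32)
    n_time = values.shape[2]
    times = (np.arange(n_time) - n_time // 2) * step
    return AlignedTensor(values=values, times=times,
                         unit_ids=np.arange(values.shape[0]),
                         trial_ids=np.arange(values.shape[1]), step=step)


def make_model(n_units, k=3, seed=0):
    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.normal(size=(n_units, k)))
    axes = AxisSet(a0=np.zeros(k), a1=rng.normal(size=k),
                   m_contra=rng.normal(size=k), m_ipsi=rng.normal(size=k))
    return StateSpaceModel(W=W, S=np.zeros((1, k)), variance_explained=np.ones(k) / k,
                           column_means=np.zeros(n_units), unit_ids=np.arange(n_units)), axes


class TestShuffles:
    def test_counts_preserved_and_deterministic(self):
        labels = np.array([True] * 7 + [False] * 12)
        p1 = shuffle_conditions(labels, 200, seed=5, n_units=4)
        p2 = shuffle_conditions(labels, 200, seed=5, n_units=4)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (4, 200, 19)
        assert (p1.sum(axis=2) == 7).all()
        # units are shuffled independently
        assert not np.array_equal(p1[0], p1[1])

    def test_two_trial_partitions_equiprobable(self):
        """1 trial per condition: both assignments drawn with p ~ 0.5."""
        labels = np.array([True, False])
        parts = shuffle_conditions(labels, 4000, seed=0, n_units=1)[0]
        frac = parts[:, 0].mean()
        assert frac == pytest.approx(0.5, abs=0.03)


class TestSurrogateProjection:
    def test_projection_identity_on_toy(self):
        """Reconstructing dx from rate differences through W equals projecting
        the shuffled condition means directly (3-unit brute force)."""
        rng = np.random.default_rng(8)
        values = rng.normal(size=(3, 10, 5)).astype(np.float32)
        labels = np.arange(10) < 4
        model, axes = make_model(3, k=2)
        spec = PermutationSpec(n_shuffles=200, seed=42, cadence=0.002)
        times, obs, surr = surrogate_statistic(make_tensor(values), labels, model, spec)

        # brute force: same partitions, explicit mean difference, then project
        all_parts = shuffle_conditions(labels, 200, seed=42, n_units=3)
        exp = np.zeros((200, 5, 2))
        for u in range(3):
            parts = all_parts[u]
            for s in range(200):
                d = values[u, parts[s]].mean(axis=0) - values[u, ~parts[s]].mean(axis=0)
                exp[s, :, :] += np.outer(d, model.W[u])
        np.testing.assert_allclose(surr, np.sqrt((exp ** 2).sum(axis=2)), atol=1e-4)
        # observed equals the unshuffled condition difference through W
        d_obs = values[:, labels].mean(axis=1) - values[:, ~labels].mean(axis=1)
        np.testing.assert_allclose(obs, np.sqrt((((d_obs.T @ model.W)) ** 2).sum(axis=1)),
                                   atol=1e-5)

    def test_identical_conditions_give_zero_observed(self):
        values = np.tile(np.arange(4.0)[None, :, None], (2, 1, 3)).astype(np.float32)
        values[:, 2:, :] = values[:, :2, :]  # c2 duplicates c1
        labels = np.array([True, True, False, False])
        model, axes = make_model(2, k=2)
        spec = PermutationSpec(n_shuffles=100, seed=0, cadence=0.002)
        _, obs, surr = surrogate_statistic(make_tensor(values), labels, model, spec)
        np.testing.assert_allclose(obs, 0.0, atol=1e-6)
        assert (surr >= 0).all()  # Euclidean statistic is non-negative

    def test_label_swap_leaves_euclidean_unchanged(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(5, 12, 4)).astype(np.float32)
        labels = np.arange(12) < 6
        model, axes = make_model(5)
        spec = PermutationSpec(n_shuffles=400, seed=3, cadence=0.002)
        _, obs1, _ = surrogate_statistic(make_tensor(values), labels, model, spec)
        _, obs2, _ = surrogate_statistic(make_tensor(values), ~labels, model, spec)
        np.testing.assert_allclose(obs1, obs2, atol=1e-5)


class TestPvalues:
    SPEC = PermutationSpec(n_shuffles=100, seed=0)

    def test_add_one_rule_extremes(self):
        surr = np.linspace(0, 1, 100)[:, None]
        res = pointwise_pvalues(np.array([2.0]), surr, self.SPEC)
        assert res.p[0] == pytest.approx(1 / 101)
        res = pointwise_pvalues(np.array([-1.0]), surr, self.SPEC)
        assert res.p[0] == pytest.approx(1.0)

    def test_observed_at_median_is_half(self):
        rng = np.random.default_rng(0)
        surr = rng.normal(size=(1000, 1))
        spec = PermutationSpec(n_shuffles=1000, seed=0)
        res = pointwise_pvalues(np.array([np.median(surr)]), surr, spec)
        assert res.p[0] == pytest.approx(0.5, abs=0.05)

    def test_two_tailed_symmetric(self):
        rng = np.random.default_rng(1)
        surr = rng.normal(size=(1000, 1))
        spec = PermutationSpec(n_shuffles=1000, seed=0, statistic="initiation_coord")
        p_hi = pointwise_pvalues(np.array([2.5]), surr, spec).p[0]
        p_lo = pointwise_pvalues(np.array([-2.5]), surr, spec).p[0]
        assert p_hi < 0.05 and p_lo < 0.05

    def test_significance_epochs_are_maximal_runs(self):
        spec = PermutationSpec(n_shuffles=100, seed=0)
        surr = np.zeros((100, 6)) + np.linspace(0, 1, 100)[:, None]
        obs = np.array([2.0, 2.0, -1.0, 2.0, 2.0, 2.0])
        res = pointwise_pvalues(obs, surr, spec, times=np.arange(6) * 0.004)
        assert res.epochs == [(0.0, 0.004), (0.012, 0.020)]


class TestEpochTest:
    def test_single_sample_window_matches_pointwise(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(6, 16, 3)).astype(np.float32)
        labels = np.arange(16) < 8
        model, axes = make_model(6)
        spec = PermutationSpec(n_shuffles=300, seed=9, cadence=0.002)
        tensor = make_tensor(values)
        res_e = epoch_test(tensor, labels, model, (0.0, 0.0), spec, axes,
                           statistics=("euclidean_10d",))["euclidean_10d"]
        _, obs, surr = surrogate_statistic(tensor, labels, model, spec)
        i0 = 1  # t = 0 is the middle of three samples
        assert res_e.scalar_observed == pytest.approx(obs[i0], abs=1e-6)
        np.testing.assert_allclose(res_e.p, pointwise_pvalues(obs[i0:i0 + 1],
                                                              surr[:, i0:i0 + 1], spec).p)

    def test_null_rejection_rate_near_alpha(self):
        """Quick null calibration (the full 500x500 check lives in acceptance)."""
        model, axes = make_model(10)
        labels = np.arange(16) < 8
        rng = np.random.default_rng(0)
        ps = []
        for d in range(150):
            vals = rng.normal(size=(10, 16, 1)).astype(np.float32)
            tensor = make_tensor(vals)
            res = epoch_test(tensor, labels, model, (0.0, 0.0),
                             PermutationSpec(n_shuffles=200, seed=d), axes,
                             statistics=("selection_coord",))["selection_coord"]
            ps.append(res.scalar_p)
        rate = np.mean(np.array(ps) < 0.05)
        assert rate == pytest.approx(0.05, abs=0.05)

    def test_power_monotone_in_effect_size(self):
        """Rejection frequency does not decrease along a 3-point effect grid."""
        model, axes = make_model(15, seed=2)
        w = axes.initiation_direction @ model.W.T  # unit-space direction
        labels = np.arange(20) < 10
        rates = []
        for effect in (0.0, 0.4, 0.8):
            rej = 0
            rng = np.random.default_rng(100)
            for d in range(25):
                vals = rng.normal(size=(15, 20, 1)).astype(np.float32)
                vals[:, labels, 0] += effect * w[:, None] / np.linalg.norm(w)
                res = epoch_test(make_tensor(vals), labels, model, (0.0, 0.0),
                                 PermutationSpec(n_shuffles=200, seed=d), axes,
                                 statistics=("initiation_coord",))["initiation_coord"]
                rej += res.significant[0]
            rates.append(rej / 25)
        assert rates[0] <= rates[1] + 0.08 and rates[1] <= rates[2] + 0.08
        assert rates[2] > rates[0]

    def test_run_state_separation_shares_shuffles(self, session_data):
        """All three statistics derive from one surrogate reconstruction and
        detect the planted pre-Go condition shift with the planted signs."""
        from gpstop.pipeline import _mask
        sd = session_data
        go = sd.tensors["go_cue"]
        m_my = _mask(sd.df, go, condition="maybe_stop_contra")
        m_no = _mask(sd.df, go, condition="no_stop")
        both = m_my | m_no
        res = epoch_test(go.select_trials(both), m_my[both], sd.model, (-0.1, 0.0),
                         PermutationSpec(n_shuffles=300, seed=1), sd.axes,
                         statistics=("euclidean_10d", "initiation_coord", "selection_coord"))
        assert res["euclidean_10d"].scalar_p < 0.05
        assert res["initiation_coord"].scalar_observed < 0  # farther from initiation
        assert res["selection_coord"].scalar_observed < 0   # biased toward ipsi
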