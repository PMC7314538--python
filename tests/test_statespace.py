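"""Population matrix assembly, PCA, axis anchoring and projection."""

import numpy as np
import pytest

from gpstop.rates import AlignedTensor
from gpstop.statespace import (AxisSet, DegenerateAxisError,
                               build_population_matrix, define_axes, fit_pca,
                               full_space_model, project_alignment)

RNG = np.random.default_rng(12345)


def random_pm(n_units=20, n_time=251, rng=RNG):
    avg_c = rng.normal(size=(n_units, n_time))
    avg_i = rng.normal(size=(n_units, n_time))
    times = (np.arange(n_time) - n_time // 2) * 0.002
    return build_population_matrix(avg_c.copy(), avg_i.copy(), times)


class TestPopulationMatrix:
    def test_shape_and_centering(self):
        pm = random_pm(n_units=3)
        assert pm.R.shape == (502, 3)
        np.testing.assert_allclose(pm.R.sum(axis=0), 0.0, atol=1e-9)

    def test_constant_unit_becomes_zero_column(self):
        avg = np.full((1, 251), 3.7)
        pm = build_population_matrix(avg, avg, np.arange(251) * 0.002)
        np.testing.assert_allclose(pm.R, 0.0, atol=1e-12)

    def test_recentering_is_identity(self):
        pm = random_pm()
        pm2 = build_population_matrix(pm.block("contra").T, pm.block("ipsi").T, pm.times)
        np.testing.assert_allclose(pm2.R, pm.R, atol=1e-12)
        np.testing.assert_allclose(pm2.column_means, 0.0, atol=1e-12)

    def test_units_with_missing_condition_dropped(self):
        avg_c = RNG.normal(size=(4, 251))
        avg_i = RNG.normal(size=(4, 251))
        avg_i[2, 10] = np.nan
        pm = build_population_matrix(avg_c, avg_i, np.arange(251) * 0.002)
        assert pm.n_units == 3 and 2 not in pm.unit_ids


class TestPca:
    def test_matches_covariance_eigendecomposition(self):
        """Independent oracle: eigen-decomposition of R'R gives the same
        spectrum and (up to sign) the same principal directions as the SVD."""
        rng = np.random.default_rng(99)
        avg_c = rng.normal(size=(20, 251))
        avg_i = rng.normal(size=(20, 251))
        pm = build_population_matrix(avg_c, avg_i, np.arange(251) * 0.002)
        model = fit_pca(pm, k=10)

        evals, evecs = np.linalg.eigh(pm.R.T @ pm.R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(model.variance_explained,
                                   (evals / evals.sum())[:10], atol=1e-8)
        for k in range(10):
            dot = abs(model.W[:, k] @ evecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_weights_and_score_identity(self):
        pm = random_pm()
        model = fit_pca(pm, k=10)
        np.testing.assert_allclose(model.W.T @ model.W, np.eye(10), atol=1e-9)
        np.testing.assert_allclose(model.S, pm.R @ model.W, atol=1e-9)
        assert (np.diff(model.variance_explained) <= 1e-12).all()

    def test_full_rank_reconstruction(self):
        pm = random_pm(n_units=8)
        model = fit_pca(pm, k=8)
        np.testing.assert_allclose(model.S @ model.W.T, pm.R, atol=1e-8)

    def test_planar_data_truncates_k(self):
        rng = np.random.default_rng(7)
        basis = rng.normal(size=(2, 15))
        coeffs = rng.normal(size=(502, 2))
        R = coeffs @ basis
        pm = build_population_matrix(R[:251].T, R[251:].T, np.arange(251) * 0.002)
        model = fit_pca(pm, k=10)
        assert model.k <= 3  # rank 2 data (+1 for centering numerics)
        assert model.variance_explained[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_deterministic(self):
        pm = random_pm()
        m1, m2 = fit_pca(pm), fit_pca(pm)
        np.testing.assert_array_equal(m1.W, m2.W)
        for k in range(m1.k):
            assert m1.W[np.argmax(np.abs(m1.W[:, k])), k] > 0


class TestAxes:
    def test_anchor_scalings_exact(self, session_data):
        """The four anchors map to 0/1 (Initiation) and -1/+1 (Selection)."""
        for axes in (session_data.axes, session_data.full_axes):
            assert axes.initiation_coord(axes.a0) == pytest.approx(0.0, abs=1e-12)
            assert axes.initiation_coord(axes.a1) == pytest.approx(1.0, abs=1e-12)
            assert axes.selection_coord(axes.m_ipsi) == pytest.approx(-1.0, abs=1e-12)
            assert axes.selection_coord(axes.m_contra) == pytest.approx(1.0, abs=1e-12)

    def test_label_swap_negates_selection(self):
        rng = np.random.default_rng(3)
        a0, a1 = rng.normal(size=10), rng.normal(size=10)
        tc, ti = rng.normal(size=(251, 10)), rng.normal(size=(251, 10))
        ax = define_axes(a0, a1, tc, ti)
        ax_swapped = define_axes(a0, a1, ti, tc)
        pts = rng.normal(size=(5, 10))
        np.testing.assert_allclose(ax_swapped.selection_coord(pts),
                                   -ax.selection_coord(pts), atol=1e-12)
        np.testing.assert_allclose(ax_swapped.initiation_coord(pts),
                                   ax.initiation_coord(pts), atol=1e-12)

    def test_degenerate_axis_raises(self):
        v = np.ones(10)
        with pytest.raises(DegenerateAxisError):
            AxisSet(a0=v, a1=v, m_contra=v, m_ipsi=np.zeros(10))


class TestProjection:
    def test_training_average_reproduces_scores(self, session_data):
        """Projecting the training condition averages recovers S = R W."""
        from gpstop.pipeline import _mask
        sd = session_data
        co = sd.tensors["center_out"]
        m_c = _mask(sd.df, co, outcome="correct_go", condition="no_stop",
                    go_direction="contra")
        traj = project_alignment(co, sd.model, m_c)
        np.testing.assert_allclose(traj.positions, sd.model.S[:co.n_time], atol=1e-6)

    def test_affine_equivariance(self):
        """A constant per-unit rate offset changes no scaled coordinate."""
        rng = np.random.default_rng(17)
        n_units, n_time = 12, 51
        avg_c = rng.normal(size=(n_units, n_time))
        avg_i = rng.normal(size=(n_units, n_time))
        times = (np.arange(n_time) - n_time // 2) * 0.002
        shift = rng.normal(size=n_units)

        def fit(ac, ai, extra):
            pm = build_population_matrix(ac, ai, times)
            model = fit_pca(pm, k=5)
            tc = model.project(ac.T)
            ti = model.project(ai.T)
            ax = define_axes(np.stack([tc[0], ti[0]]), np.stack([tc[25], ti[25]]), tc, ti)
            probe = model.project((extra).T)
            return ax.initiation_coord(probe), ax.selection_coord(probe)

        probe = rng.normal(size=(n_units, 7))
        i1, s1 = fit(avg_c, avg_i, probe)
        i2, s2 = fit(avg_c + shift[:, None], avg_i + shift[:, None], probe + shift[:, None])
        np.testing.assert_allclose(i1, i2, atol=1e-8)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_unit_mismatch_rejected(self, session_data):
        co = session_data.tensors["center_out"]
        bad = AlignedTensor(values=co.values[:-1], times=co.times,
                            unit_ids=co.unit_ids[:-1], trial_ids=co.trial_ids,
                            event=co.event, step=co.step)
        with pytest.raises(ValueError):
            project_alignment(bad, session_data.model)


class TestFullSpace:
    def test_low_rank_data_agrees_with_pc10(self):
        """When >=99% of variance lies in 10 dims, full-space and PC-space
        scaled coordinates agree to within 2% RMS."""
        rng = np.random.default_rng(31)
        n_units, n_time = 40, 251
        t = np.linspace(0, 1, n_time)
        ramp = np.clip(2 * t - 0.5, 0, 1)
        bump = np.exp(-0.5 * ((t - 0.6) / 0.15) ** 2)
        wi, ws = rng.normal(size=n_units), rng.normal(size=n_units)
        avg_c = wi[:, None] * ramp + ws[:, None] * bump + 0.01 * rng.normal(size=(n_units, n_time))
        avg_i = wi[:, None] * ramp - ws[:, None] * bump + 0.01 * rng.normal(size=(n_units, n_time))
        times = (np.arange(n_time) - n_time // 2) * 0.002
        pm = build_population_matrix(avg_c, avg_i, times)

        coords = {}
        for name, model in [("pc", fit_pca(pm, k=10)), ("full", full_space_model(pm))]:
            tc, ti = model.project(avg_c.T), model.project(avg_i.T)
            ax = define_axes(np.stack([tc[0], ti[0]]),
                             np.stack([tc[n_time // 2], ti[n_time // 2]]), tc, ti)
            coords[name] = np.stack([ax.initiation_coord(tc), ax.selection_coord(tc),
                                     ax.initiation_coord(ti), ax.selection_coord(ti)])
        num = np.sqrt(np.mean((coords["pc"] - coords["full"]) ** 2))
        den = np.sqrt(np.mean(coords["full"] ** 2))
        assert num / den < 0.02

    def test_full_space_scalings_exact(self, session_data):
        ax = session_data.full_axes
        assert ax.space == "full"
        assert ax.initiation_coord(ax.a1) == pytest.approx(1.0, abs=1e-12)
        assert ax.selection_coord(ax.m_contra) == pytest.approx(1.0, abs=1e-12)

    def test_selection_direction_recovers_planted_loadings(self):
        """Low noise: full-space Selection direction aligns with the planted
        per-unit selection loadings (cosine >= 0.9)."""
        import gpstop as g
        from gpstop.params import params_to_dict
        from gpstop.pipeline import AnalysisConfig, prepare_session
        task = g.TaskParams(n_go_trials=130, n_stop_trials=30, iti_range=(1.0, 2.0))
        pop = g.PopulationParams(n_neurons=40, noise_sd=0.0)
        cfg = AnalysisConfig(seed=21, generator=params_to_dict(task, g.RaceParams(), pop),
                             n_shuffles=300)
        sd = prepare_session(cfg)
        w = sd.ground_truth.sel_loadings[sd.pm.unit_ids]
        d = sd.full_axes.selection_direction
        cos = d @ w / (np.linalg.norm(d) * np.linalg.norm(w))
        assert cos >= 0.9
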