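import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lineattractor as la
from lineattractor.rslds import ObservedActivity, RSLDSParams


def _single_state_params(A, C=None, Q=1e-12, S=1e-12, N=4):
    A = np.atleast_2d(np.asarray(A, dtype=float))
    D = A.shape[0]
    C = np.ones((N, D)) if C is None else np.asarray(C, dtype=float)
    return RSLDSParams(As=A[None], bs=np.zeros((1, D)), Qs=[np.eye(D) * Q],
                       Rs=np.zeros((1, 1, D)), rs=np.zeros((1, 1)),
                       C=C, d=np.zeros(C.shape[0]), S=np.full(C.shape[0], S))


class TestSampling:
    def test_deterministic_geometric_decay(self):
        p = _single_state_params(0.5 * np.eye(2))
        lat, _ = la.sample_rslds(p, 10, seed=0, x0=[1.0, 1.0])
        expect = 0.5 ** np.arange(1, 11)
        np.testing.assert_allclose(lat.x[0], expect, atol=1e-5)
        np.testing.assert_allclose(lat.x[1], expect, atol=1e-5)

    def test_single_state_constant_z(self):
        p = _single_state_params(0.9 * np.eye(2), Q=0.01, S=0.01)
        lat, _ = la.sample_rslds(p, 200, seed=1)
        assert np.all(lat.z == 0)

    def test_transition_frequencies_match_softmax(self):
        """Monte-Carlo transition frequencies agree with the recurrent
        softmax probabilities within 3 SE."""
        Rs = np.zeros((2, 2, 2))
        Rs[:, 1, 0] = 3.0
        rs = np.zeros((2, 2))
        rs[:, 1] = -0.5
        p = RSLDSParams(As=np.tile(np.diag([0.95, 0.8]), (2, 1, 1)),
                        bs=np.zeros((2, 2)),
                        Qs=np.tile(np.eye(2) * 0.04, (2, 1, 1)),
                        Rs=Rs, rs=rs, C=np.ones((3, 2)), d=np.zeros(3),
                        S=np.full(3, 0.01))
        lat, _ = la.sample_rslds(p, 60000, seed=4)
        x, z = lat.x, lat.z
        sel = (z[:-1] == 0) & (np.abs(x[0, :-1] - 0.5) < 0.1)
        assert sel.sum() > 500
        emp = (z[1:][sel] == 1).mean()
        pred = np.mean([p.transition_probs(0, x[:, t])[1]
                        for t in np.flatnonzero(sel)])
        se = np.sqrt(pred * (1 - pred) / sel.sum())
        assert abs(emp - pred) < 3 * se

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            RSLDSParams(As=np.eye(2)[None], bs=np.zeros((1, 2)),
                        Qs=[[[1.0, 2.0], [2.0, 1.0]]],
                        Rs=np.zeros((1, 1, 2)), rs=np.zeros((1, 1)),
                        C=np.ones((3, 2)), d=np.zeros(3), S=np.ones(3))


class TestFitting:
    def test_near_noiseless_reconstruction(self):
        cfg = la.GeneratorConfig(emission_noise_frac=0.01, seed=2)
        s = la.generate_line_attractor_session(cfg)
        p, _ = la.fit_rslds(s.activity, 2, 2, inputs=s.input_schedule,
                            max_iter=30, seed=0)
        lat = la.infer_latents(p, s.activity, inputs=s.input_schedule)
        yhat = p.C @ lat.x + p.d[:, None]
        tot = s.activity.y - s.activity.y.mean(axis=1, keepdims=True)
        r2 = 1 - ((s.activity.y - yhat) ** 2).sum() / (tot ** 2).sum()
        assert r2 > 0.99

    def test_elbo_non_decreasing(self, default_session):
        _, diag = la.fit_rslds(default_session.activity, 2, 2,
                               inputs=default_session.input_schedule,
                               max_iter=20, tol=1e-10, seed=0)
        tr = diag.elbo_trace
        assert np.all(np.isfinite(tr))
        diffs = np.diff(tr)
        assert np.all(diffs >= -1e-6 * (1.0 + np.abs(tr[:-1])))

    def test_white_noise_has_no_structure(self):
        y = np.random.default_rng(0).standard_normal((30, 1500))
        cv = la.cross_validated_r2(y, 2, 2, folds=5, seed=0, max_iter=15)
        assert cv < 10.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            la.fit_rslds(np.zeros((5, 200)), 2, 1)

    def test_stationary_covariance_round_trip(self):
        """sample -> fit -> sample preserves the stationary covariance of y
        (median relative error over seeds below 15%)."""
        errs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            C = rng.normal(0, 1, (20, 2))
            true = RSLDSParams(
                As=np.tile(np.diag([0.98, 0.8]), (2, 1, 1)),
                bs=np.zeros((2, 2)),
                Qs=np.tile(np.diag([0.02, 0.1]), (2, 1, 1)),
                Rs=np.zeros((2, 2, 2)), rs=np.tile([0.0, -0.7], (2, 1)),
                C=C, d=np.zeros(20), S=np.full(20, 0.05))
            _, act = la.sample_rslds(true, 4000, seed=seed + 10)
            p, _ = la.fit_rslds(act, 2, 2, max_iter=25, seed=0)
            _, act2 = la.sample_rslds(p, 4000, seed=seed + 50)
            c1, c2 = np.cov(act.y), np.cov(act2.y)
            errs.append(np.linalg.norm(c2 - c1) / np.linalg.norm(c1))
        assert np.median(errs) < 0.15


class TestInference:
    def test_noiseless_alignment(self, default_session):
        gt = default_session.ground_truth
        u = default_session.input_schedule[None, :2000]
        lat0, _ = la.sample_rslds(gt, 2000, inputs=u, seed=9)
        y = gt.C @ lat0.x + gt.d[:, None]
        inf = la.infer_latents(gt, ObservedActivity(y), inputs=u)
        for dim in range(2):
            r2 = max(np.corrcoef(inf.x[k], lat0.x[dim])[0, 1] ** 2
                     for k in range(2))
            assert r2 > 0.99

    def test_linear_gaussian_limit_is_least_squares(self):
        rng = np.random.default_rng(0)
        C = rng.normal(0, 1, (10, 2))
        p = _single_state_params(0.9 * np.eye(2), C=C, Q=1e4, S=1e-10)
        y = rng.normal(0, 1, (10, 300))
        inf = la.infer_latents(p, y)
        ls = np.linalg.lstsq(C, y, rcond=None)[0]
        np.testing.assert_allclose(inf.x, ls, atol=1e-3)

    def test_constant_input_gives_constant_latents(self):
        p = _single_state_params(0.9 * np.eye(2), Q=0.01, S=0.01)
        y = np.ones((4, 100)) * 2.0
        inf = la.infer_latents(p, y)
        assert np.ptp(inf.x[:, 5:-5], axis=1).max() < 1e-6

    def test_dimension_mismatch_rejected(self, default_session):
        with pytest.raises(ValueError):
            la.infer_latents(default_session.ground_truth,
                             np.ones((3, 100)))


class TestForwardSimulation:
    def test_identity_dynamics_constant(self):
        p = _single_state_params(np.eye(2), Q=1e-6, S=1.0)
        tr = la.forward_simulate(p, [1.0, 2.0], T=20)
        np.testing.assert_allclose(tr.x, [[1.0] * 20, [2.0] * 20])

    def test_contraction_norm_decreases(self):
        p = _single_state_params(np.diag([0.9, 0.5]), Q=1e-6, S=1.0)
        tr = la.forward_simulate(p, [1.0, 1.0], T=50)
        norms = np.linalg.norm(tr.x, axis=0)
        assert np.all(np.diff(norms) < 0)

    def test_pulse_inputs_integrate_along_slow_dimension(self, quiet_session):
        gt = quiet_session.ground_truth
        u = np.zeros((1, 900))
        for k in range(4):
            u[0, 100 + k * 200:120 + k * 200] = 30.0
        tr = la.forward_simulate(gt, [0.0, 0.0], inputs=u, T=900)
        ends = [tr.x[0, 100 + (k + 1) * 200 - 5] for k in range(4)]
        assert all(b > a for a, b in zip(ends, ends[1:]))


class TestEmissionGeometry:
    def test_dimension_weight_assignment(self):
        p = _single_state_params(
            0.9 * np.eye(2), C=np.array([[0.9, 0.0], [0.0, 0.0]]), S=1.0)
        w = la.dimension_weights(p)
        assert w.label.tolist() == ["x1", "neither"]
        assert w.weight_x1[0] == pytest.approx(0.9)

    def test_top_neurons_ranking_and_ties(self):
        p = _single_state_params(
            0.9 * np.eye(2),
            C=np.array([[3.0, 0], [1.0, 0], [2.0, 0]]), S=1.0)
        sel = la.select_top_neurons(la.dimension_weights(p), 1, k=2)
        np.testing.assert_array_equal(sel, [0, 2])
        p_eq = _single_state_params(
            0.9 * np.eye(2), C=np.ones((4, 2)), S=1.0)
        sel_eq = la.select_top_neurons(la.dimension_weights(p_eq), 1, k=2)
        np.testing.assert_array_equal(sel_eq, [0, 1])
        with pytest.raises(ValueError):
            la.select_top_neurons(la.dimension_weights(p_eq), 1, k=9)

    def test_planted_top5_within_planted_group(self, default_session):
        w = la.dimension_weights(default_session.ground_truth)
        sel = la.select_top_neurons(w, 1, k=5)
        planted = np.flatnonzero(default_session.positions.labels == "x1")
        assert set(sel).issubset(set(planted))

    @pytest.mark.parametrize("C,expect", [
        (np.array([[1.0, 0.0], [0.0, 1.0]]), 90.0),
        (np.array([[1.0, 1.0], [1.0, 1.0]]), 0.0),
        (np.array([[1.0, 1.0], [0.0, 1.0]]), 45.0),
    ])
    def test_subspace_angle_closed_forms(self, C, expect):
        assert la.subspace_angle(C) == pytest.approx(expect, abs=1e-6)

    def test_subspace_angle_zero_column_rejected(self):
        with pytest.raises(ValueError):
            la.subspace_angle(np.array([[1.0, 0.0], [1.0, 0.0]]))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_softmax_transition_rows_normalize(seed):
    """Transition probabilities sum to one at any evaluated latent point."""
    rng = np.random.default_rng(seed)
    K = int(rng.integers(1, 4))
    p = RSLDSParams(As=np.tile(0.5 * np.eye(2), (K, 1, 1)),
                    bs=np.zeros((K, 2)), Qs=np.tile(np.eye(2), (K, 1, 1)),
                    Rs=rng.normal(0, 2, (K, K, 2)), rs=rng.normal(0, 2, (K, K)),
                    C=np.ones((3, 2)), d=np.zeros(3), S=np.ones(3))
    x = rng.normal(0, 5, 2)
    for k in range(K):
        probs = p.transition_probs(k, x)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(probs >= 0)
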