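import numpy as np
import pytest

import lineattractor as la
from lineattractor.perturbation import (
    DisplacementMetrics,
    connectivity_fraction,
    evoked_projection,
    influence_scores,
    isi_peak_table,
    project_onto_dimension,
    simulate_targeted_stim,
    stability_connectivity_correlation,
    state_space_displacement,
)
from lineattractor.rslds import LatentTrajectory, ObservedActivity


def _protocol(session, group="x1", n_pulses=6, gain=1.0):
    targets = np.flatnonzero(session.positions.labels == group)[:5]
    return la.generate_stim_protocol(n_pulses, 20.0, 2.0, 20.0, targets,
                                     start_s=60.0, gain=gain)


class TestSimulatedStim:
    def test_zero_gain_identity(self, quiet_session):
        prot = _protocol(quiet_session, gain=0.0)
        pert = simulate_targeted_stim(quiet_session, prot)
        np.testing.assert_array_equal(pert.y, quiet_session.activity.y)

    def test_unknown_targets_rejected(self, quiet_session):
        prot = la.generate_stim_protocol(2, 20.0, 2.0, 20.0, [10 ** 6],
                                         start_s=60.0)
        with pytest.raises(ValueError):
            simulate_targeted_stim(quiet_session, prot)

    def test_x1_stim_integrates_across_pulses(self, quiet_session):
        prot = _protocol(quiet_session, "x1")
        ev = evoked_projection(quiet_session, prot, 1)
        tab = isi_peak_table(ev, prot, 10.0)
        assert tab.integration
        diffs = np.diff(np.concatenate([[tab.baseline_mean], tab.isi_means[:3]]))
        assert np.all(diffs > 0)

    def test_x2_stim_returns_to_baseline(self, quiet_session):
        prot = _protocol(quiet_session, "x2")
        ev = evoked_projection(quiet_session, prot, 2)
        peak = ev.max()
        ends = [ev[int(np.floor(b * 10)) - 1] for _, b in prot.isi_windows]
        assert np.abs(ends).max() < 0.05 * peak


class TestProjection:
    def test_noiseless_projection_recovers_latent(self):
        cfg = la.GeneratorConfig(emission_noise_frac=0.0, seed=4)
        s = la.generate_line_attractor_session(cfg)
        proj = project_onto_dimension(s.activity, s.ground_truth, 1,
                                      method="pinv")
        r2 = np.corrcoef(proj, s.latents.x[0])[0, 1] ** 2
        assert r2 > 0.99

    def test_constant_activity_constant_projection(self, quiet_session):
        y = ObservedActivity(np.ones_like(quiet_session.activity.y) * 0.3)
        proj = project_onto_dimension(y, quiet_session.ground_truth, 1,
                                      method="pinv")
        assert np.ptp(proj) < 1e-9

    def test_invalid_dimension_rejected(self, quiet_session):
        with pytest.raises(ValueError):
            project_onto_dimension(quiet_session.activity,
                                   quiet_session.ground_truth, 3)

    def test_x1_stim_moves_x1_not_x2(self, quiet_session):
        prot = _protocol(quiet_session, "x1")
        ev1 = evoked_projection(quiet_session, prot, 1)
        ev2 = evoked_projection(quiet_session, prot, 2)
        # the slow dimension accumulates; the fast one shows only transient
        # pulse-locked deflections
        last_isi = slice(int(130 * 10), int(150 * 10))
        assert ev1[last_isi].mean() > 5 * abs(ev2[last_isi].mean())


class TestISITable:
    def test_flat_series(self):
        prot = la.generate_stim_protocol(4, 20.0, 2.0, 20.0, [0], start_s=30.0)
        tab = isi_peak_table(np.zeros(2000), prot, 10.0)
        assert np.allclose(tab.isi_means, tab.baseline_mean)
        assert not tab.integration
        assert tab.saturation_pulse is None

    def test_planted_integrator_saturates_after_third_pulse(self, quiet_session):
        prot = _protocol(quiet_session, "x1")
        ev = evoked_projection(quiet_session, prot, 1)
        tab = isi_peak_table(ev, prot, 10.0)
        assert tab.integration
        assert tab.saturation_pulse in (3, 4)

    def test_fast_dimension_no_integration_flag(self, quiet_session):
        prot = _protocol(quiet_session, "x2")
        ev = evoked_projection(quiet_session, prot, 2)
        tab = isi_peak_table(ev, prot, 10.0)
        assert not tab.integration


class TestDisplacement:
    def test_stationary_trajectory(self):
        prot = la.generate_stim_protocol(3, 20.0, 2.0, 20.0, [0], start_s=10.0)
        lat = LatentTrajectory(x=np.ones((2, 900)), z=np.zeros(900, dtype=int))
        d = state_space_displacement(lat, prot, 10.0)
        assert np.allclose(d.d_stim_end, 0.0)
        assert np.allclose(d.d_post_stim, 0.0)

    def test_3_4_5_distance(self):
        prot = la.generate_stim_protocol(1, 20.0, 2.0, 20.0, [0], start_s=1.0)
        x = np.zeros((2, 300))
        x[:, 10:] = np.array([[3.0], [4.0]])
        lat = LatentTrajectory(x=x, z=np.zeros(300, dtype=int))
        d = state_space_displacement(lat, prot, 10.0)
        assert d.d_stim_end[0] == pytest.approx(5.0)

    def test_integrator_displacement_grows_fast_dim_returns(self, quiet_session):
        gt = quiet_session.ground_truth
        for group, dim in (("x1", 0), ("x2", 1)):
            prot = _protocol(quiet_session, group)
            pert = simulate_targeted_stim(quiet_session, prot)
            base = la.infer_latents(gt, quiet_session.activity)
            stim = la.infer_latents(gt, pert)
            ev = LatentTrajectory(x=stim.x - base.x, z=stim.z)
            d = state_space_displacement(ev, prot, 10.0)
            if group == "x1":
                assert d.d_post_stim[2] > d.d_post_stim[0]
            else:
                assert d.d_post_stim[-1] < 0.1 * d.d_stim_end.max()

    def test_translation_invariance(self):
        """Adding a constant to all latents leaves displacements unchanged."""
        prot = la.generate_stim_protocol(2, 20.0, 2.0, 20.0, [0], start_s=5.0)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (2, 600))
        lat = LatentTrajectory(x=x, z=np.zeros(600, dtype=int))
        lat2 = LatentTrajectory(x=x + 7.3, z=lat.z)
        d1 = state_space_displacement(lat, prot, 10.0)
        d2 = state_space_displacement(lat2, prot, 10.0)
        np.testing.assert_allclose(d1.d_stim_end, d2.d_stim_end)
        np.testing.assert_allclose(d1.d_post_stim, d2.d_post_stim)

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError):
            DisplacementMetrics(d_stim_end=np.array([-1.0]),
                                d_post_stim=np.array([0.0]))


class TestInfluence:
    def test_uncoupled_scores_near_zero(self):
        sess, prots, pos, labels = la.generate_unitary_stim_cohort(
            coupling_density=0.0, cross_amp_z=0.0, seed=0)
        infl = influence_scores(sess, prots, pos, labels)
        assert np.abs(infl.pair_scores("x1", "x1")).max() < 0.2

    def test_coupled_ensemble_separates_pair_classes(self):
        sess, prots, pos, labels = la.generate_unitary_stim_cohort(seed=3)
        infl = influence_scores(sess, prots, pos, labels)
        within = infl.pair_scores("x1", "x1")
        across = infl.pair_scores("x1", "x2")
        assert np.median(within[within > 0.5]) > across.max()

    def test_followers_inside_exclusion_radius_all_masked(self):
        sess, prots, pos, labels = la.generate_unitary_stim_cohort(
            n_x1=4, n_x2=3, seed=1)
        pos.table["x_um"] = 10.0
        pos.table["y_um"] = 10.0
        infl = influence_scores(sess, prots, pos, labels)
        assert np.all(infl.masked)

    def test_missing_positions_rejected(self):
        sess, prots, pos, labels = la.generate_unitary_stim_cohort(
            n_x1=3, n_x2=2, seed=1)
        with pytest.raises(ValueError):
            influence_scores(sess, prots, None, labels)

    def test_shifted_pulse_null_has_zero_mean_influence(self):
        """Influence on uncoupled data is centred on zero when pulse times
        are circularly shifted relative to any structure."""
        sess, prots, pos, labels = la.generate_unitary_stim_cohort(
            coupling_density=0.0, cross_amp_z=0.0, n_x1=8, n_x2=6, seed=5)
        infl = influence_scores(sess, prots, pos, labels)
        scores = infl.pair_scores("x1", "x1")
        assert abs(scores.mean()) < 3 * scores.std() / np.sqrt(len(scores))


class TestConnectivityFraction:
    def test_simple_threshold_count(self):
        from lineattractor.perturbation import InfluenceMatrix
        labels = np.array(["x1", "x1", "x1", "x1", "x2"])
        score = np.full((2, 5), np.nan)
        score[0, 1:4] = [1.0, 2.0, 3.0]
        score[0, 4] = 2.5
        score[1, 4] = 1.0
        infl = InfluenceMatrix(score=score, target_ids=np.array([0, 1]),
                               labels=labels, masked=np.isnan(score))
        assert connectivity_fraction(infl) == pytest.approx(1 / 3)

    def test_all_below_threshold(self):
        from lineattractor.perturbation import InfluenceMatrix
        labels = np.array(["x1", "x1", "x2"])
        score = np.array([[np.nan, 0.1, 5.0]])
        infl = InfluenceMatrix(score=score, target_ids=np.array([0]),
                               labels=labels, masked=np.isnan(score))
        assert connectivity_fraction(infl) == 0.0

    def test_empty_class_rejected(self):
        from lineattractor.perturbation import InfluenceMatrix
        labels = np.array(["x1", "x1"])
        score = np.array([[np.nan, 1.0]])
        infl = InfluenceMatrix(score=score, target_ids=np.array([0]),
                               labels=labels, masked=np.isnan(score))
        with pytest.raises(ValueError):
            connectivity_fraction(infl)


class TestStabilityConnectivity:
    def test_collinear(self):
        tau = np.arange(10.0)
        r2, slope, p = stability_connectivity_correlation(tau, 2 * tau + 1)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_independent_lists(self):
        rng = np.random.default_rng(0)
        r2, _, _ = stability_connectivity_correlation(
            rng.normal(0, 1, 100), rng.normal(0, 1, 100))
        assert r2 < 0.1

    def test_shared_cause_high_r2(self):
        """Sessions whose tau and connectivity both derive from one planted
        coupling strength correlate strongly."""
        rng = np.random.default_rng(1)
        coupling = rng.uniform(0.5, 0.95, 12)
        tau = 20.0 / (1 - coupling) * (1 + 0.03 * rng.standard_normal(12))
        conn = 3.0 * coupling + 0.05 * rng.standard_normal(12)
        r2, slope, p = stability_connectivity_correlation(tau, conn)
        assert r2 > 0.8 or p < 1e-3

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            stability_connectivity_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
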