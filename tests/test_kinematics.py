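"""Kinematics stage: smoothing, stroke plane, angles, phases, wing masses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightpower.kinematics import (build_point_mass_wing,
                                    compute_advance_ratio,
                                    compute_angle_of_attack,
                                    compute_stroke_angles,
                                    detect_stroke_phases, fit_stroke_plane,
                                    smooth_trajectories, spanwise_mass_profile)
from flightpower.synthetic_data import make_morphology


class TestSmoother:
    def test_constant_trajectory_unchanged(self):
        y = np.full((50, 3), 2.5)
        out = smooth_trajectories(y, 10.0)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_zero_penalty_is_identity(self, rng):
        y = rng.normal(size=(80, 3))
        np.testing.assert_allclose(smooth_trajectories(y, 0.0), y, atol=1e-12)

    def test_reduces_noise_toward_truth(self, rng):
        t = np.linspace(0, 1, 400)
        truth = np.sin(2 * np.pi * 3 * t)
        noisy = truth + rng.normal(0, 0.05, t.shape)
        smoothed = smooth_trajectories(noisy, 50.0)
        assert np.sqrt(np.mean((smoothed - truth) ** 2)) \
            < 0.5 * np.sqrt(np.mean((noisy - truth) ** 2))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            smooth_trajectories(np.ones((10, 3)), -1.0)
        bad = np.ones((10, 3))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            smooth_trajectories(bad, 1.0)


class TestStrokePlane:
    def test_xz_plane_gives_lateral_normal(self):
        ang = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        vecs = np.column_stack([np.cos(ang), np.zeros_like(ang), np.sin(ang)])
        normal, inclination = fit_stroke_plane(vecs)
        assert abs(abs(normal[1]) - 1.0) < 1e-9
        assert inclination == pytest.approx(90.0, abs=1e-6)

    def test_recovers_generator_plane_noise_free(self, dove):
        assert dove.kin.stroke_plane_angle == pytest.approx(
            dove.recording.params.stroke_plane_angle, abs=1.8)

    def test_collinear_data_rejected(self):
        vecs = np.outer(np.linspace(1, 2, 10), [1.0, 0.5, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_stroke_plane(vecs)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_recovery_error_vanishes_with_noise(self, seed):
        """Plane recovery error is noise-bounded and -> 0 as noise -> 0."""
        gen = np.random.default_rng(seed)
        chi = gen.uniform(10, 80)
        n_true = np.array([np.sin(np.radians(chi)), 0, np.cos(np.radians(chi))])
        e1 = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(n_true, e1)
        ang = np.linspace(-1, 1, 60)
        vecs = np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2
        for noise, tol in ((0.0, 1e-6), (0.01, 3.0)):
            pts = vecs + gen.normal(0, noise, vecs.shape)
            _, inclination = fit_stroke_plane(pts)
            assert abs(inclination - chi) < tol


class TestStrokeAngles:
    def test_in_plane_vector_zero_deviation(self):
        vecs = np.array([[0.0, 1.0, 0.0], [0.5, 0.5, 0.0]])
        _, dev = compute_stroke_angles(vecs, np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(dev, 0.0, atol=1e-9)

    def test_along_normal_ninety_degrees(self):
        vecs = np.array([[0.0, 0.0, 1.0]])
        _, dev = compute_stroke_angles(vecs, np.array([0.0, 0.0, 1.0]))
        assert dev[0] == pytest.approx(90.0)

    def test_zero_length_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_stroke_angles(np.zeros((3, 3)), np.array([0, 0, 1.0]))

    def test_recovers_generated_stroke_waveform(self, dove):
        from flightpower.synthetic_data import stroke_angle_waveform
        sl, _, _ = dove.wingbeat()
        phi = dove.recording.truth["phi_landmarks"][sl]
        expected = stroke_angle_waveform(phi, dove.recording.params)
        assert np.max(np.abs(dove.kin.stroke_angle[sl] - expected)) < 1.0


class TestAngleOfAttack:
    def test_chord_parallel_to_flow_is_zero(self):
        aoa, valid = compute_angle_of_attack([[-1.0, 0, 0]], [[1.0, 0, 0]],
                                             speed_threshold=0.1)
        assert valid[0] and aoa[0] == pytest.approx(0.0)

    def test_chord_perpendicular_is_ninety(self):
        aoa, _ = compute_angle_of_attack([[0, 0, 1.0]], [[1.0, 0, 0]],
                                         speed_threshold=0.1)
        assert aoa[0] == pytest.approx(90.0)

    def test_slow_samples_masked(self):
        aoa, valid = compute_angle_of_attack(
            [[1.0, 0, 0], [1.0, 0, 0]], [[1e-9, 0, 0], [1.0, 0, 0]])
        assert not valid[0] and np.isnan(aoa[0]) and valid[1]

    def test_dove_mid_downstroke_dip(self, dove):
        """The recovered angle of attack dips to ~30.5 deg at ~27.7% of stroke."""
        sl, down, frac = dove.wingbeat()
        aoa = dove.kin.angle_of_attack[sl]
        sel = down & (frac > 0.15) & (frac < 0.40) & np.isfinite(aoa)
        dip = np.nanmin(aoa[sel])
        dip_at = frac[sel][np.nanargmin(aoa[sel])]
        assert dip == pytest.approx(30.5, abs=2.0)
        assert dip_at == pytest.approx(0.277, abs=0.03)


class TestStrokePhases:
    def test_sinusoid_splits_at_extrema(self):
        t = np.linspace(0, 2.6, 2601)
        theta = 40 * np.cos(2 * np.pi * t)
        labels, frac, beats = detect_stroke_phases(theta, t)
        assert len(beats) == 1
        a, rev, b = beats[0]
        down = labels[a:rev] == "down"
        assert down.mean() > 0.99
        assert (rev - a) / (b - a) == pytest.approx(0.5, abs=0.01)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_stroke_phases(np.ones(100), np.linspace(0, 1, 100))

    def test_dove_downstroke_fraction(self, dove):
        _, down, _ = dove.wingbeat()
        assert down.mean() == pytest.approx(0.603, abs=0.02)


class TestPointMassWing:
    @staticmethod
    def _straight_wing(n_t=11, radius=0.25):
        t = np.linspace(0, 0.01, n_t)
        sh = np.zeros((n_t, 3))
        wr = np.tile([0, 0.45 * radius, 0], (n_t, 1))
        tp = np.tile([0, radius, 0], (n_t, 1))
        return sh, wr, tp, t

    def test_masses_sum_to_wing_mass(self, dove_morph):
        sh, wr, tp, t = self._straight_wing()
        wm = build_point_mass_wing(dove_morph, sh, wr, tp, t)
        assert wm.masses.sum() == pytest.approx(dove_morph.wing_mass_single,
                                                rel=1e-9)

    def test_straight_arm_equal_stations(self, dove_morph):
        sh, wr, tp, t = self._straight_wing(radius=0.2)
        wm = build_point_mass_wing(dove_morph, sh, wr, tp, t)
        dist = np.linalg.norm(wm.positions[0], axis=1)
        np.testing.assert_allclose(dist, wm.stations * 0.2, rtol=1e-9)

    def test_radius_of_gyration_matches_direct_summation(self, dove_morph):
        sh, wr, tp, t = self._straight_wing(radius=0.2258)
        profile = spanwise_mass_profile(20)
        wm = build_point_mass_wing(dove_morph, sh, wr, tp, t,
                                   mass_profile=profile)
        # independent direct summation over the configured profile
        x = (np.arange(20) + 0.5) / 20 * 0.2258
        expected = np.sqrt(np.sum(profile * x ** 2) / profile.sum())
        assert wm.radius_of_gyration(np.zeros(3)) == pytest.approx(expected,
                                                                   rel=1e-9)

    def test_kinetic_energy_invariant_under_rotation(self, dove, rng):
        """World-frame rigid rotation leaves point-mass kinetic energy alone."""
        from scipy.spatial.transform import Rotation

        wm = dove.wing_left
        ke = wm.kinetic_energy()
        rot = Rotation.random(rng=rng).as_matrix()
        lm = dove.kin.landmarks
        t = dove.kin.time
        wm_rot = build_point_mass_wing(dove.morphology, lm["shoulder"] @ rot.T,
                                       lm["wrist"] @ rot.T, lm["XP9"] @ rot.T, t)
        np.testing.assert_allclose(wm_rot.kinetic_energy(), ke, rtol=1e-8)

    def test_nonpositive_wing_mass_rejected(self, dove_morph):
        sh, wr, tp, t = self._straight_wing()
        with pytest.raises(ValueError):
            build_point_mass_wing(dove_morph, sh, wr, tp, t,
                                  mass_profile=-np.ones(20))


class TestAdvanceRatio:
    def test_hovering_is_zero(self):
        assert compute_advance_ratio(0.0, np.array([5.0, 6.0])) == 0.0

    def test_equal_speeds_is_one(self):
        assert compute_advance_ratio(3.0, np.array([3.0, 3.0])) == 1.0

    def test_zero_wingtip_speed_rejected(self):
        with pytest.raises(ValueError):
            compute_advance_ratio(1.0, np.zeros(5))

    def test_dove_preset_near_printed_value(self, dove):
        sl, _, _ = dove.wingbeat()
        tip_speed = np.linalg.norm(dove.kin.tip_velocity[sl], axis=1)
        j = compute_advance_ratio(dove.recording.params.forward_speed, tip_speed)
        assert j == pytest.approx(0.14, abs=0.02)


def test_velocity_matches_analytic_derivative():
    """Central differences reproduce the derivative of a known trajectory."""
    t = np.linspace(0, 1, 1001)
    pos = np.column_stack([np.sin(2 * np.pi * t), t ** 2, np.cos(2 * np.pi * t)])
    from flightpower.kinematics import differentiate

    vel = differentiate(pos, t)
    expected = np.column_stack([2 * np.pi * np.cos(2 * np.pi * t), 2 * t,
                                -2 * np.pi * np.sin(2 * np.pi * t)])
    np.testing.assert_allclose(vel[2:-2], expected[2:-2], atol=2e-4)
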