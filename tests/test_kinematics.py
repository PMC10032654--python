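"""Midline resampling, frequency, joint angles, phase lags, amplitudes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thrustwake.foil import TrajectorySeries
from thrustwake.kinematics import (JointAngleSeries, MidlineTrack,
                                   amplitude_profile, circular_cross_correlation,
                                   gap_distance, joint_angles, phase_difference,
                                   phase_lags, principal_frame, resample_midline,
                                   tailbeat_frequency, unwrap_phases)
from thrustwake.synth import simulate_swimmer

from conftest import A_TAIL, validation_swimmer


def straight_track(n_frames=10, n_markers=9, fps=125.0):
    xy = np.zeros((n_frames, n_markers, 2))
    xy[:, :, 0] = np.linspace(0.0, 0.19, n_markers)
    return MidlineTrack(np.arange(n_frames) / fps, xy, 0.19, fps)


class TestResampleMidline:
    def test_spline_passes_through_raw_markers_at_keyframes(self):
        track = simulate_swimmer(validation_swimmer(duration=0.2, n_markers=9))
        res = resample_midline(track, n_out=201, keyframe_stride=6)
        for f in (0, 6, 12):
            for marker in track.xy[f]:
                d = np.linalg.norm(res.xy[f] - marker, axis=1).min()
                assert d < 1e-4  # nearest discrete station on the spline

    def test_straight_midline_gives_collinear_equispaced_stations(self):
        res = resample_midline(straight_track(), n_out=25)
        assert np.allclose(res.xy[0][:, 1], 0.0)
        steps = np.diff(res.xy[0][:, 0])
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_midway_frame_is_mean_of_keyframe_stations(self):
        track = simulate_swimmer(validation_swimmer(duration=0.2, n_markers=9))
        res = resample_midline(track, n_out=31, keyframe_stride=2)
        np.testing.assert_allclose(res.xy[1], 0.5 * (res.xy[0] + res.xy[2]),
                                   atol=1e-12)

    def test_too_few_output_stations_rejected(self):
        track = simulate_swimmer(validation_swimmer(duration=0.1, n_markers=9))
        with pytest.raises(ValueError):
            resample_midline(track, n_out=5)


class TestTailbeatFrequency:
    def test_pure_two_hertz_swimmer(self):
        track = simulate_swimmer(validation_swimmer(f=2.0, duration=3.0))
        assert tailbeat_frequency(track) == pytest.approx(2.0, rel=0.01)

    def test_constant_track_has_no_peaks(self):
        with pytest.raises(ValueError, match="oscillate|peaks"):
            tailbeat_frequency(straight_track(n_frames=200))

    def test_insufficient_cycles_rejected(self):
        track = simulate_swimmer(validation_swimmer(f=1.0, duration=2.0))
        with pytest.raises(ValueError, match="cycles|maxima"):
            tailbeat_frequency(track)


class TestJointAngles:
    def test_straight_and_rigidly_rotated_midlines_have_zero_angles(self):
        track = straight_track()
        assert np.allclose(joint_angles(resample_midline(track, 25), N=20).angles,
                           0.0, atol=1e-12)
        rotated = track.rotated(0.8, about=(0.05, 0.0))
        assert np.allclose(joint_angles(resample_midline(rotated, 25), N=20).angles,
                           0.0, atol=1e-10)

    @pytest.mark.parametrize("theta", [0.3, 1.0])
    def test_circular_arc_turning_shared_equally(self, theta):
        # Geometric oracle: chords of N equal sub-arcs meet at theta / N.
        N = 20
        radius = 0.19 / theta
        phi = np.linspace(0.0, theta, 401)
        arc = radius * np.column_stack([np.sin(phi), 1.0 - np.cos(phi)])
        xy = np.repeat(arc[None], 3, axis=0)
        track = MidlineTrack(np.arange(3) / 125.0, xy, 0.19, 125.0)
        angles = joint_angles(track, N=N).angles[0]
        np.testing.assert_allclose(angles, theta / N, rtol=1e-3)

    def test_degenerate_segment_rejected(self):
        xy = np.zeros((3, 9, 2))
        xy[:, :, 0] = np.concatenate([[0.0, 0.0], np.linspace(0.05, 0.19, 7)])
        track = MidlineTrack(np.arange(3) / 125.0, xy, 0.19, 125.0)
        with pytest.raises(ValueError):
            joint_angles(track, N=8)

    def test_requires_enough_stations(self):
        with pytest.raises(ValueError, match="resample"):
            joint_angles(straight_track(n_markers=9), N=20)


class TestPhaseLags:
    @pytest.mark.parametrize("lam,expected_waves", [(1.0, 1.0), (0.5, 2.0)])
    def test_whole_wave_counts(self, lam, expected_waves):
        track = simulate_swimmer(validation_swimmer(lam=lam))
        T = 1.0 / tailbeat_frequency(track)
        angles = joint_angles(resample_midline(track, keyframe_stride=1), N=20)
        result = phase_lags(angles, T=T)
        assert result.overall == pytest.approx(expected_waves * 2 * math.pi, rel=0.02)
        # lambda * delta_Phi = 2 pi by definition
        assert result.wavelength * result.overall == pytest.approx(2 * math.pi)
        assert result.overall == pytest.approx(result.delta_phi.sum())

    def test_standing_wave_has_zero_overall_lag(self):
        t = np.arange(500) / 125.0
        profile = 0.5 + 0.4 * np.sin(np.linspace(0.0, 2.0 * math.pi, 19))
        angles = JointAngleSeries(0.05 * np.outer(np.sin(2 * math.pi * 2 * t), profile),
                                  20, t, 125.0)
        result = phase_lags(angles, T=0.5)
        assert abs(result.overall) < 0.05

    def test_zero_variance_signal_rejected(self):
        t = np.arange(500) / 125.0
        sig = np.zeros((500, 19))
        sig[:, 1:] = 0.05 * np.sin(2 * math.pi * 2 * t)[:, None]
        angles = JointAngleSeries(sig, 20, t, 125.0)
        with pytest.raises(ValueError, match="variance"):
            phase_lags(angles, T=0.5)

    def test_summation_modes_are_consistent(self):
        track = simulate_swimmer(validation_swimmer())
        T = 1.0 / tailbeat_frequency(track)
        angles = joint_angles(resample_midline(track, keyframe_stride=1), N=20)
        full = phase_lags(angles, T=T, mode="full")
        endpoint = phase_lags(angles, T=T, mode="endpoint")
        plain = phase_lags(angles, T=T, mode="plain")
        assert plain.overall < endpoint.overall < full.overall
        assert full.overall == pytest.approx(plain.overall * 20 / 18, rel=1e-9)

    def test_noisy_markers_recovered_within_tolerance(self):
        # 1 mm tracking noise on a 0.19 m body, digitised with 9 markers.
        for seed in (0, 1, 2, 3):
            spec = validation_swimmer(n_markers=9, noise_sd=1e-3, seed=seed)
            track = simulate_swimmer(spec)
            freq = tailbeat_frequency(track)
            assert freq == pytest.approx(2.0, rel=0.02)
            angles = joint_angles(resample_midline(track, keyframe_stride=1), N=20)
            result = phase_lags(angles, T=1.0 / freq, spatial_window=9)
            assert result.overall == pytest.approx(2 * math.pi, rel=0.05)

    def test_tapered_envelope_biases_wave_slower_near_head(self):
        # With an amplitude envelope growing towards the tail the
        # curvature wave is genuinely slower than the displacement wave:
        # the summed lags under-run 2 pi / lam by a few percent.  This is
        # a property of the waveform, not an estimator artefact.
        spec = validation_swimmer(a_head=0.25 * A_TAIL)
        track = simulate_swimmer(spec)
        T = 1.0 / tailbeat_frequency(track)
        angles = joint_angles(resample_midline(track, keyframe_stride=1), N=20)
        tapered = phase_lags(angles, T=T).overall
        assert 0.85 * 2 * math.pi < tapered < 2 * math.pi


class TestAmplitudeProfile:
    def test_tail_amplitude_recovered(self):
        track = simulate_swimmer(validation_swimmer())
        profile = amplitude_profile(track)
        assert profile.amplitude[-1] == pytest.approx(A_TAIL, rel=0.02)

    def test_rotation_invariance(self):
        track = simulate_swimmer(validation_swimmer())
        rotated = track.rotated(math.radians(30.0))
        a = amplitude_profile(track).amplitude
        b = amplitude_profile(rotated).amplitude
        np.testing.assert_allclose(a, b, rtol=0.01)

    def test_zero_lateral_motion_gives_zero_amplitudes(self):
        profile = amplitude_profile(straight_track(n_frames=20))
        np.testing.assert_allclose(profile.amplitude, 0.0, atol=1e-15)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            amplitude_profile(straight_track(n_frames=2))


class TestPhaseDifference:
    def _series(self, delay, T=0.5, fs=125.0, dur=4.0):
        t = np.arange(int(dur * fs)) / fs
        return TrajectorySeries(t, np.sin(2 * math.pi / T * (t - delay)))

    def test_identical_signals_have_zero_phase(self):
        a = self._series(0.0)
        assert phase_difference(a, a, 0.5) == pytest.approx(0.0, abs=1e-6)

    def test_quarter_period_delay_maps_to_half_pi(self):
        a = self._series(0.0)
        b = self._series(0.125)
        assert phase_difference(a, b, 0.5) == pytest.approx(math.pi / 2, rel=1e-3)

    def test_insufficient_overlap_rejected(self):
        a = self._series(0.0, dur=4.0)
        b = self._series(0.0, dur=1.0)
        with pytest.raises(ValueError, match="cycles"):
            phase_difference(a, b, 0.5)

    def test_unwrap_orders_by_distance(self):
        d = np.array([0.3, 0.1, 0.2])
        p = np.array([0.5, 0.5, 3.5])
        d_s, unw = unwrap_phases(d, p)
        np.testing.assert_array_equal(d_s, [0.1, 0.2, 0.3])
        assert np.all(np.diff(d_s) > 0)


class TestCircularCrossCorrelation:
    def test_known_integer_shift(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=64)
        for shift in (0, 5, 40):
            b = np.roll(a, shift)
            c = circular_cross_correlation(a - a.mean(), b - b.mean())
            assert int(np.argmax(c)) == shift


class TestGapDistance:
    def test_examples(self):
        assert gap_distance((0.0, 0.0), (0.0, 0.0)) == 0.0
        assert gap_distance((0.0, 0.0), (0.3, 0.0)) == pytest.approx(0.3)
        window = np.array([[0.1, 0.0], [0.3, 0.0]])
        assert gap_distance((0.0, 0.0), window) == pytest.approx(0.2)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(ax=st.floats(-1, 1), ay=st.floats(-1, 1), bx=st.floats(-1, 1),
           by=st.floats(-1, 1), tx=st.floats(-5, 5), ty=st.floats(-5, 5),
           ang=st.floats(0, 2 * math.pi))
    def test_rigid_transform_invariance(self, ax, ay, bx, by, tx, ty, ang):
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        a, b = np.array([ax, ay]), np.array([bx, by])
        d0 = gap_distance(a, b)
        d1 = gap_distance(rot @ a + (tx, ty), rot @ b + (tx, ty))
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestRigidMotionInvariance:
    def test_translation_leaves_kinematics_unchanged(self):
        track = simulate_swimmer(validation_swimmer(duration=3.0))
        moved = track.translated((1.2, -0.4))
        assert tailbeat_frequency(moved) == pytest.approx(
            tailbeat_frequency(track), rel=1e-9)
        a1 = amplitude_profile(track).amplitude
        a2 = amplitude_profile(moved).amplitude
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_rotation_leaves_frequency_and_lags_unchanged(self):
        track = simulate_swimmer(validation_swimmer(duration=3.0))
        rotated = track.rotated(0.6)
        f1 = tailbeat_frequency(track)
        f2 = tailbeat_frequency(rotated)
        assert f2 == pytest.approx(f1, rel=1e-6)
        T = 1.0 / f1
        l1 = phase_lags(joint_angles(resample_midline(track, keyframe_stride=1)), T=T)
        l2 = phase_lags(joint_angles(resample_midline(rotated, keyframe_stride=1)), T=T)
        assert l2.overall == pytest.approx(l1.overall, rel=1e-6)
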