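"""Filtering, differentiation, peak summaries, and impact energy."""

import numpy as np
import pytest

from impactkit.kinematics import (
    GRAVITY,
    MarkerTrack,
    derive_kinematics,
    filter_track,
    impact_energy,
    summarize_peaks,
)


def make_track(m1, frame_rate=5000.0, m2_offset=(-0.015, 0.0), **kw):
    m1 = np.asarray(m1, dtype=float)
    n = len(m1)
    return MarkerTrack(
        time=np.arange(n) / frame_rate,
        marker1=m1,
        marker2=m1 + np.asarray(m2_offset),
        frame_rate=frame_rate,
        **kw,
    )


def sinusoid_track(freq, frame_rate=5000.0, n=1000, amp=1e-3):
    t = np.arange(n) / frame_rate
    m1 = np.column_stack([amp * np.sin(2 * np.pi * freq * t), np.zeros(n)])
    return make_track(m1, frame_rate)


class TestFilterTrack:
    def test_constant_track_unchanged(self):
        track = make_track(np.tile([0.01, 0.02], (200, 1)))
        out = filter_track(track)
        np.testing.assert_allclose(out.marker1, track.marker1, atol=1e-12)

    @pytest.mark.parametrize(
        "freq, min_gain, max_gain",
        [
            (50.0, 0.99, 1.01),  # passband: amplitude preserved within 1%
            (2000.0, 0.0, 0.01),  # stopband: attenuated below 1%
        ],
    )
    def test_frequency_response(self, freq, min_gain, max_gain):
        track = sinusoid_track(freq)
        out = filter_track(track, cutoff_hz=400.0)
        # compare steady-state amplitudes away from the edges
        sl = slice(200, -200)
        gain = np.abs(out.marker1[sl, 0]).max() / np.abs(track.marker1[sl, 0]).max()
        assert min_gain <= gain <= max_gain

    def test_effective_cutoff_is_minus_3db(self):
        track = sinusoid_track(400.0)
        out = filter_track(track, cutoff_hz=400.0)
        sl = slice(300, -300)
        gain = np.abs(out.marker1[sl, 0]).max() / np.abs(track.marker1[sl, 0]).max()
        assert gain == pytest.approx(2.0 ** -0.5, rel=0.02)

    def test_passband_idempotence(self):
        track = sinusoid_track(50.0)
        once = filter_track(track)
        twice = filter_track(once)
        sl = slice(200, -200)
        ratio = np.abs(twice.marker1[sl, 0]).max() / np.abs(once.marker1[sl, 0]).max()
        assert abs(ratio - 1.0) < 0.02

    def test_zero_phase_no_peak_shift(self):
        t = np.arange(500) / 5000.0
        pulse = 1e-3 * np.exp(-0.5 * ((t - 0.05) / 0.004) ** 2)
        track = make_track(np.column_stack([pulse, np.zeros_like(pulse)]))
        out = filter_track(track)
        assert np.argmax(out.marker1[:, 0]) == np.argmax(track.marker1[:, 0])

    def test_cutoff_above_nyquist_rejected(self):
        track = sinusoid_track(50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            filter_track(track, cutoff_hz=2500.0)


class TestDeriveKinematics:
    def test_linear_motion_constant_velocity(self):
        t = np.arange(200) / 5000.0
        v = np.array([1.5, -0.5])
        track = make_track(np.outer(t, v))
        ks = derive_kinematics(track)
        speed = np.hypot(*v)
        np.testing.assert_allclose(ks.linear_velocity[1:-1], speed, rtol=1e-9)
        np.testing.assert_allclose(ks.linear_acceleration[1:-1], 0.0, atol=1e-6)

    def test_quadratic_motion_matches_analytic_derivatives(self):
        # position = 0.5*a*t^2 along x: velocity a*t, acceleration a
        t = np.arange(200) / 5000.0
        a = 300.0
        track = make_track(np.column_stack([0.5 * a * t**2, np.zeros_like(t)]))
        ks = derive_kinematics(track)
        np.testing.assert_allclose(ks.linear_velocity[2:-2], a * t[2:-2], rtol=1e-9)
        np.testing.assert_allclose(ks.linear_acceleration[2:-2], a, rtol=1e-6)

    def test_horizontal_marker_pair_zero_deflection(self):
        t = np.arange(100) / 5000.0
        track = make_track(np.column_stack([t, np.zeros_like(t)]))
        np.testing.assert_allclose(derive_kinematics(track).deflection, 0.0, atol=1e-12)

    def test_constant_rotation_rate(self):
        rate = 100.0  # rad/s
        n, fr = 300, 5000.0
        t = np.arange(n) / fr
        theta = rate * t
        m1 = np.zeros((n, 2))
        m2 = m1 - 0.015 * np.column_stack([np.cos(theta), np.sin(theta)])
        track = MarkerTrack(time=t, marker1=m1, marker2=m2, frame_rate=fr)
        ks = derive_kinematics(track)
        np.testing.assert_allclose(ks.angular_velocity[1:-1], rate, rtol=1e-9)
        np.testing.assert_allclose(ks.angular_acceleration[2:-2], 0.0, atol=1e-5)

    def test_deflection_unwraps_past_pi(self):
        n, fr = 300, 5000.0
        t = np.arange(n) / fr
        theta = 80.0 * t  # reaches 4.8 rad, beyond +pi
        m1 = np.zeros((n, 2))
        m2 = m1 - 0.015 * np.column_stack([np.cos(theta), np.sin(theta)])
        track = MarkerTrack(time=t, marker1=m1, marker2=m2, frame_rate=fr)
        ks = derive_kinematics(track)
        baseline = theta[:5].mean()
        assert ks.deflection[-1] == pytest.approx(theta[-1] - baseline, rel=1e-9)

    def test_displacement_is_distance_from_baseline(self):
        # stationary lead-in, then motion along y: displacement equals the
        # distance from the (stationary) pre-impact position
        t = np.arange(100) / 5000.0
        y = np.where(t > 0.005, 2.0 * (t - 0.005), 0.0)
        track = make_track(np.column_stack([np.zeros_like(t), y]))
        ks = derive_kinematics(track)
        assert ks.displacement[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(ks.displacement, y, atol=1e-12)

    def test_too_few_baseline_frames_rejected(self):
        track = make_track(np.zeros((60, 2)))
        with pytest.raises(ValueError, match="baseline"):
            derive_kinematics(track, baseline_frames=100)


class TestMarkerTrackValidation:
    def test_nonuniform_sampling_rejected(self):
        t = np.arange(60) / 5000.0
        t[30] += 1e-5
        with pytest.raises(ValueError, match="uniformly"):
            MarkerTrack(time=t, marker1=np.zeros((60, 2)), marker2=np.zeros((60, 2)),
                        frame_rate=5000.0)

    def test_missing_frames_rejected(self):
        m = np.zeros((60, 2))
        m[5, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            MarkerTrack(time=np.arange(60) / 5000.0, marker1=m, marker2=np.zeros((60, 2)),
                        frame_rate=5000.0)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            MarkerTrack(time=np.arange(10) / 5000.0, marker1=np.zeros((10, 2)),
                        marker2=np.zeros((10, 2)), frame_rate=5000.0)


class TestSummarizePeaks:
    def _impulse_series(self, peak_vel, animal_id="a"):
        # half-sine velocity pulse along x, integrated to positions
        fr, n = 5000.0, 250
        t = np.arange(n) / fr
        vel = np.zeros(n)
        window = (t > 0.002) & (t < 0.012)
        vel[window] = peak_vel * np.sin(np.pi * (t[window] - 0.002) / 0.01)
        pos = np.cumsum(vel) / fr
        track = make_track(np.column_stack([pos, np.zeros_like(pos)]),
                           animal_id=animal_id)
        return derive_kinematics(track)

    def test_delta_v_equals_peak_velocity(self):
        table = summarize_peaks([self._impulse_series(4.0)])
        assert table.delta_v == table["linear_velocity"].value
        assert table.delta_v == pytest.approx(4.0, rel=0.01)

    def test_identical_impacts_zero_cv(self):
        series = [self._impulse_series(4.0, a) for a in ("a", "b", "c")]
        table = summarize_peaks(series)
        assert all(cv == pytest.approx(0.0, abs=1e-9) for cv in table.cv.values())

    def test_cv_is_sample_sd_over_mean(self):
        # per-animal peaks {2, 3, 4} -> CV = SD({2,3,4}, ddof=1)/3
        series = [self._impulse_series(v, a) for v, a in [(2, "a"), (3, "b"), (4, "c")]]
        table = summarize_peaks(series)
        values = [2.0, 3.0, 4.0]
        expected = np.std(values, ddof=1) / np.mean(values)
        assert table.cv["linear_velocity"] == pytest.approx(expected, rel=0.02)

    def test_day_averaging_pools_within_animal(self):
        # one animal with two impacts {2, 4} and one with {3, 3}: per-animal
        # means are both 3 so the CV vanishes
        series = [
            self._impulse_series(2.0, "a"),
            self._impulse_series(4.0, "a"),
            self._impulse_series(3.0, "b"),
            self._impulse_series(3.0, "b"),
        ]
        table = summarize_peaks(series)
        assert table.n_animals == 2
        assert table.cv["linear_velocity"] == pytest.approx(0.0, abs=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_peaks([])


class TestImpactEnergy:
    def test_mouse_head_energy_reported(self):
        # 3.4 g head, 6.6 m/s velocity change -> 0.074 J, reported 0.07 J
        res = impact_energy(0.0034, 6.6)
        assert res.kinetic_energy == pytest.approx(0.5 * 0.0034 * 6.6**2)
        assert res.reported == 0.07

    def test_piston_energy(self):
        # 50 g piston at 4.472 m/s carries the 0.5 J input energy
        assert impact_energy(0.050, 4.472).reported == 0.50

    def test_zero_velocity(self):
        assert impact_energy(1.0, 0.0).kinetic_energy == 0.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            impact_energy(0.0, 1.0)


def test_gravity_constant_is_standard():
    assert GRAVITY == 9.81
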