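"""Synthetic-data generators: constrained trajectories, microglia images,
open-field tracks, calibration tables."""

from dataclasses import replace

import numpy as np
import pytest

from impactkit import behavior, calibration, histomorph
from impactkit.kinematics import GRAVITY, derive_kinematics, filter_track, summarize_peaks
from impactkit.synthio import (
    MORPHOLOGIES,
    MOUSE_IMPACT_PEAKS,
    DEFAULT_NOISE_SD,
    ImpactSpec,
    InfeasibleImpactSpec,
    gen_calibration_table,
    gen_impact_trajectory,
    gen_microglia_image,
    gen_openfield_track,
)

ZERO_SPEC = ImpactSpec(
    peak_displacement=0, t_displacement=1e-3,
    peak_deflection=0, t_deflection=1e-3,
    peak_velocity=0, t_velocity=1e-3,
    peak_acceleration=0, t_acceleration=1e-3,
    peak_ang_velocity=0, t_ang_velocity=1e-3,
    peak_ang_acceleration=0, t_ang_acceleration=1e-3,
)


class TestImpactSpecValidation:
    def test_negative_peak_rejected(self):
        with pytest.raises(ValueError, match="peak_velocity"):
            replace(MOUSE_IMPACT_PEAKS, peak_velocity=-1.0)

    def test_peak_time_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            replace(MOUSE_IMPACT_PEAKS, t_acceleration=5e-3)

    def test_time_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            replace(MOUSE_IMPACT_PEAKS, t_displacement=0.05)


class TestImpactTrajectory:
    def test_zero_motion_spec_gives_stationary_track(self):
        track = gen_impact_trajectory(ZERO_SPEC)
        assert np.ptp(track.marker1, axis=0).max() == 0.0
        assert np.ptp(track.marker2, axis=0).max() == 0.0

    def test_rigid_body_marker_separation(self, mouse_track):
        d = np.linalg.norm(mouse_track.marker1 - mouse_track.marker2, axis=1)
        np.testing.assert_allclose(d, d[0], rtol=1e-12)

    def test_stationary_start(self, mouse_track):
        assert np.ptp(mouse_track.marker1[:5], axis=0).max() == 0.0

    def test_oracle_peaks_match_constraints(self, mouse_track):
        # independent oracle: unfiltered central differences on positions
        ks = derive_kinematics(mouse_track)
        v_peak = ks.linear_velocity[1:-1].max()
        d_peak = ks.displacement[1:-1].max()
        assert v_peak == pytest.approx(6.6, rel=0.02)
        assert d_peak == pytest.approx(49.6e-3, rel=0.02)
        assert np.abs(ks.deflection[1:-1]).max() == pytest.approx(2.6, rel=0.02)
        assert np.abs(ks.angular_velocity[1:-1]).max() == pytest.approx(305.8, rel=0.02)
        assert ks.linear_acceleration[1:-1].max() == pytest.approx(
            385.3 * GRAVITY, rel=0.02
        )

    def test_displacement_returns_after_peak(self, mouse_track):
        ks = derive_kinematics(mouse_track)
        i_peak = int(np.argmax(ks.displacement))
        assert ks.displacement[-1] < 0.8 * ks.displacement[i_peak]

    def test_noise_changes_with_seed_but_not_constraints(self):
        spec = replace(MOUSE_IMPACT_PEAKS, noise_sd=DEFAULT_NOISE_SD)
        t1 = gen_impact_trajectory(spec, seed=1)
        t2 = gen_impact_trajectory(spec, seed=2)
        t1b = gen_impact_trajectory(spec, seed=1)
        assert not np.array_equal(t1.marker1, t2.marker1)
        np.testing.assert_array_equal(t1.marker1, t1b.marker1)
        # underlying noiseless track still satisfies the velocity constraint
        clean = gen_impact_trajectory(replace(spec, noise_sd=0.0))
        ks = derive_kinematics(clean)
        assert ks.linear_velocity[1:-1].max() == pytest.approx(6.6, rel=0.02)

    def test_noise_requires_seed(self):
        spec = replace(MOUSE_IMPACT_PEAKS, noise_sd=DEFAULT_NOISE_SD)
        with pytest.raises(ValueError, match="seed"):
            gen_impact_trajectory(spec)

    def test_infeasible_spec_names_constraint(self):
        # peak acceleration below the mean acceleration required to reach
        # peak velocity in time: impossible for any rise profile
        bad = replace(MOUSE_IMPACT_PEAKS, peak_acceleration=500.0)
        with pytest.raises(InfeasibleImpactSpec, match="linear"):
            gen_impact_trajectory(bad)

    def test_round_trip_on_scaled_down_spec(self):
        # a second feasible constraint set: all peaks at 70% of the mouse
        # values with the same timing
        spec = replace(
            MOUSE_IMPACT_PEAKS,
            peak_displacement=0.7 * 49.6e-3,
            peak_deflection=0.7 * 2.6,
            peak_velocity=0.7 * 6.6,
            peak_acceleration=0.7 * 385.3 * GRAVITY,
            peak_ang_velocity=0.7 * 305.8,
            peak_ang_acceleration=0.7 * 253.6e3,
        )
        track = gen_impact_trajectory(spec)
        table = summarize_peaks([derive_kinematics(filter_track(track))])
        assert table["linear_velocity"].value == pytest.approx(0.7 * 6.6, rel=0.05)
        assert table["angular_acceleration"].value == pytest.approx(
            0.7 * 253.6e3, rel=0.05
        )


class TestMicrogliaImages:
    def test_unknown_morphology_rejected(self):
        with pytest.raises(ValueError, match="morphology"):
            gen_microglia_image("reactive", 256, 0)

    def test_small_canvas_rejected(self):
        with pytest.raises(ValueError, match="size_px"):
            gen_microglia_image("ramified", 64, 0)

    @pytest.mark.parametrize("morphology", MORPHOLOGIES)
    def test_single_connected_component(self, morphology):
        from scipy import ndimage

        img = gen_microglia_image(morphology, 256, seed=3)
        _, n = ndimage.label(img)
        assert n == 1

    def test_ramified_cell_is_branched(self):
        from skimage.morphology import skeletonize
        from scipy import ndimage

        img = gen_microglia_image("ramified", 256, seed=0)
        skel = skeletonize(img)
        neighbours = ndimage.convolve(skel.astype(int), np.ones((3, 3)), mode="constant")
        branch_points = ((neighbours >= 4) & skel).sum()
        assert branch_points >= 10  # several branch generations

    def test_amoeboid_is_compact_blob(self):
        img = gen_microglia_image("amoeboid", 256, seed=0)
        # compactness: perimeter^2 / (4 pi area) close to 1 for a smooth blob
        from impactkit.histomorph import _outline

        area = img.sum()
        perimeter = _outline(img).sum()
        assert perimeter**2 / (4 * np.pi * area) < 2.0

    def test_fractal_dimension_ordering(self):
        means = {
            m: np.mean(
                [histomorph.boxcount_fd(gen_microglia_image(m, 256, s)) for s in range(20)]
            )
            for m in MORPHOLOGIES
        }
        assert (
            means["ramified"] > means["hypertrophic"] > means["bushy"] > means["amoeboid"]
        )


class TestOpenFieldTracks:
    @pytest.mark.parametrize("frac", [0.0, 0.25, 0.5, 2 / 3, 1.0])
    def test_realized_peripheral_fraction(self, frac):
        track = gen_openfield_track(frac, duration=600, rate=10, seed=5)
        ti = behavior.thigmotaxis_index(track)
        # TI = 2*frac - 1 when the realized fraction matches the target
        assert ti == pytest.approx(2 * frac - 1, abs=0.04)

    def test_two_thirds_peripheral_gives_ti_one_third(self):
        track = gen_openfield_track(2 / 3, duration=600, rate=10, seed=1)
        assert behavior.thigmotaxis_index(track) == pytest.approx(1 / 3, abs=0.02)

    def test_track_stays_in_arena(self):
        track = gen_openfield_track(0.5, duration=60, rate=10, seed=2)
        assert track["x"].between(0, 14).all()
        assert track["y"].between(0, 24).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            gen_openfield_track(1.2, 60, 10, 0)


class TestCalibrationTables:
    def test_default_pressures_give_24_rows(self):
        table = gen_calibration_table()
        assert len(table) == 24  # 8 pressures x 3 replicates
        assert sorted(table["pressure_psi"].unique()) == [0.5, 1, 1.5, 2, 3, 5, 7, 10]

    def test_noiseless_table_recovers_coefficients_exactly(self):
        coeffs = (-0.02, 0.8, 0.25)
        table = gen_calibration_table(coeffs=coeffs, noise_sd=0.0)
        curve = calibration.fit_calibration(table, piston_mass=0.05)
        np.testing.assert_allclose(curve.coefficients, coeffs, atol=1e-10)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_r2_below_one_and_coefficients_recovered(self):
        # over 100 seeds the mean fitted coefficients stay within 3 standard
        # errors of the truth
        coeffs = np.array([-0.015, 0.75, 0.30])
        fits = []
        for seed in range(100):
            table = gen_calibration_table(noise_sd=0.05, seed=seed)
            curve = calibration.fit_calibration(table, piston_mass=0.05)
            assert curve.r_squared < 1.0
            fits.append(curve.coefficients)
        fits = np.array(fits)
        err = np.abs(fits.mean(axis=0) - coeffs)
        se = fits.std(axis=0, ddof=1) / np.sqrt(len(fits))
        assert (err <= 3 * se + 1e-12).all()

    def test_empty_pressures_rejected(self):
        with pytest.raises(ValueError):
            gen_calibration_table(pressures=[])
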