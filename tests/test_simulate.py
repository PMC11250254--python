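import math

import numpy as np
import pandas as pd
import pytest

from cardioulm.geometry import CartesianGrid
from cardioulm.simulate import (MotionModel, PSFModel, Scatterer,
                                apply_tissue_motion, make_vessel_phantom,
                                render_ceus_stack, simulate_rf,
                                simulate_transit)
from conftest import point_ground_truth


class TestVesselPhantom:
    def test_parallel_pair_separation_by_construction(self):
        tree = make_vessel_phantom({"family": "parallel_pair",
                                    "separation_um": 300.0,
                                    "center_um": (0.0, 40e3)}, seed=0)
        assert tree.n_segments == 2
        assert tree.min_centreline_distance() == pytest.approx(300.0)

    def test_empty_spec_gives_empty_tree(self):
        assert make_vessel_phantom({}, seed=0).n_segments == 0

    def test_deterministic_for_fixed_seed(self):
        spec = {"family": "branching", "levels": 3}
        a = make_vessel_phantom(spec, seed=7)
        b = make_vessel_phantom(spec, seed=7)
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa.polyline_um, sb.polyline_um)

    def test_vessel_outside_sector_rejected(self):
        with pytest.raises(ValueError):
            make_vessel_phantom({"family": "parallel_pair",
                                 "separation_um": 300.0,
                                 "center_um": (0.0, 40e3),
                                 "length_um": 10e3,
                                 "sector": {"depth_um": 30e3,
                                            "half_angle_deg": 26.5}}, seed=0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            make_vessel_phantom({"family": "helix"}, seed=0)


@pytest.fixture(scope="module")
def tree():
    return make_vessel_phantom({"family": "parallel_pair",
                                "separation_um": 1000.0,
                                "center_um": (0.0, 40e3),
                                "length_um": 8e3,
                                "mean_speed_mm_s": 20.0}, seed=0)


class TestTransit:

    def test_zero_bubble_rate_gives_no_records(self, tree):
        gt = simulate_transit(tree, 1.0, 100.0, 0.0, seed=0)
        assert len(gt.records) == 0

    def test_constant_speed_displacement_per_frame(self, tree):
        fr = 100.0
        gt = simulate_transit(tree, 1.0, fr, 20.0,
                              speed_law=lambda rng, n: np.full(n, 10.0), seed=1)
        for _, sub in gt.records.groupby("id"):
            if len(sub) < 3:
                continue
            d = np.hypot(np.diff(sub["x_um"]), np.diff(sub["z_um"]))
            # straight segment: per-frame displacement = v / frame_rate
            assert d[:-1] == pytest.approx(10.0 / fr * 1e3, rel=1e-6)

    def test_lognormal_speed_mean_matches_closed_form(self):
        mu, sigma, n = 1.0, 0.5, 20000
        rng = np.random.default_rng(3)
        from cardioulm.simulate import sample_lognormal_speeds
        s = sample_lognormal_speeds(mu, sigma, n, rng)
        mean_true = math.exp(mu + sigma**2 / 2)
        sd = math.sqrt((math.exp(sigma**2) - 1)) * mean_true
        assert abs(s.mean() - mean_true) < 3 * sd / math.sqrt(n)

    def test_velocities_are_position_finite_differences(self, tree):
        gt = simulate_transit(tree, 1.0, 100.0, 30.0, seed=2)
        for _, sub in gt.records.groupby("id"):
            if len(sub) < 2:
                continue
            vx = sub["vx_mm_s"].to_numpy()[:-1]
            dx = np.diff(sub["x_um"].to_numpy()) * 100.0 * 1e-3
            assert np.abs(vx - dx).max() < 1e-6

    def test_reproducible_for_fixed_seed(self, tree):
        a = simulate_transit(tree, 1.0, 100.0, 30.0, seed=5)
        b = simulate_transit(tree, 1.0, 100.0, 30.0, seed=5)
        pd.testing.assert_frame_equal(a.records, b.records)


class TestMotionModel:
    @pytest.fixture()
    def mm(self):
        return MotionModel(period_s=1.0, translation_um=(200.0, 400.0),
                           rotation_deg=1.0, scale=1.01,
                           nonrigid_amplitude_um=100.0, center_um=(0.0, 40e3))

    def test_periodicity(self, mm, rng):
        x = rng.uniform(-5e3, 5e3, 50)
        z = rng.uniform(30e3, 50e3, 50)
        for t in (0.13, 0.31, 0.77):
            d0 = mm.displacement(x, z, t)
            d1 = mm.displacement(x, z, t + mm.period_s)
            assert np.allclose(d0, d1, atol=1e-9)

    def test_zero_amplitude_is_identity(self, rng):
        mm = MotionModel()
        dx, dz = mm.displacement(rng.uniform(0, 1e4, 10), rng.uniform(0, 1e4, 10), 0.1)
        assert np.allclose(dx, 0) and np.allclose(dz, 0)

    def test_pure_translation_shifts_uniformly(self):
        mm = MotionModel(translation_um=(123.0, -77.0), systole_fraction=0.4)
        t_peak = 0.4 * 0.25  # mid-attack has amplitude 1
        x = np.array([0.0, 1e3, 5e3])
        z = np.array([30e3, 40e3, 50e3])
        dx, dz = mm.displacement(x, z, t_peak)
        a = mm.amplitude(t_peak)
        assert np.allclose(dx, 123.0 * a) and np.allclose(dz, -77.0 * a)

    def test_scaled_to_peak_hits_requested_amplitude(self, mm, rng):
        x = rng.uniform(-5e3, 5e3, 200)
        z = rng.uniform(30e3, 50e3, 200)
        scaled = mm.scaled_to_peak(1500.0, x, z)
        assert scaled.peak_displacement_um(x, z) == pytest.approx(1500.0, rel=1e-6)

    def test_diastole_is_static(self, mm):
        assert mm.amplitude(0.9) == 0.0  # phase 0.9 > systole fraction

    def test_bubbles_displaced_with_tissue(self, mm):
        gt = point_ground_truth([(0, 1e3, 40e3)], frame_rate_hz=100.0)
        moved = apply_tissue_motion(gt, mm)
        assert moved.motion is mm
        # frame 0 at t=0: amplitude 0, identity
        assert moved.records.loc[0, "x_um"] == pytest.approx(1e3)


class TestRenderCeus:
    def test_single_bubble_peak_at_true_position(self, small_cart_grid):
        gt = point_ground_truth([(0, 1234.0, 30e3)])
        psf = PSFModel.for_frequency(2.4)
        ceus, _ = render_ceus_stack(gt, psf, small_cart_grid, snr_db=np.inf, seed=0)
        f = ceus.frames[0]
        zi, xi = np.unravel_index(np.argmax(f), f.shape)
        assert abs(small_cart_grid.z_um[zi] - 30e3) <= small_cart_grid.dz_um / 2
        assert abs(small_cart_grid.x_um[xi] - 1234.0) <= small_cart_grid.dx_um / 2

    def test_two_distant_bubbles_give_two_components(self, small_cart_grid):
        gt = point_ground_truth([(0, -4e3, 28e3), (0, 4e3, 33e3)])
        psf = PSFModel.for_frequency(2.4)
        ceus, _ = render_ceus_stack(gt, psf, small_cart_grid, snr_db=np.inf, seed=0)
        from scipy.ndimage import label
        f = ceus.frames[0]
        _, n = label(f > 0.5 * f.max())
        assert n == 2

    def test_requested_snr_within_1db(self, small_cart_grid):
        gt = point_ground_truth([(0, 0.0, 30e3)])
        psf = PSFModel.for_frequency(2.4)
        clean, _ = render_ceus_stack(gt, psf, small_cart_grid, snr_db=np.inf, seed=0)
        noisy, _ = render_ceus_stack(gt, psf, small_cart_grid, snr_db=30.0, seed=0)
        c = clean.frames[0].astype(float)
        n = noisy.frames[0].astype(float) - c
        support = c > 1e-3 * c.max()
        snr_db = 10 * np.log10((c[support] ** 2).mean() / n.var())
        assert abs(snr_db - 30.0) < 1.0

    def test_bit_identical_for_fixed_seed(self, small_cart_grid):
        gt = point_ground_truth([(0, 0.0, 30e3)])
        psf = PSFModel.for_frequency(2.4)
        a, _ = render_ceus_stack(gt, psf, small_cart_grid, snr_db=30.0, seed=9)
        b, _ = render_ceus_stack(gt, psf, small_cart_grid, snr_db=30.0, seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_rendered_point_fwhm_matches_model(self, small_cart_grid):
        # splatting self-consistency at the 30 mm anchor
        gt = point_ground_truth([(0, 0.0, 30e3)])
        psf = PSFModel.for_frequency(2.4)
        ceus, _ = render_ceus_stack(gt, psf, small_cart_grid, snr_db=np.inf, seed=0)
        f = ceus.frames[0]
        zi, xi = np.unravel_index(np.argmax(f), f.shape)
        profile = f[zi]
        above = np.nonzero(profile > 0.5 * profile.max())[0]
        fwhm = (above[-1] - above[0] + 1) * small_cart_grid.dx_um
        assert fwhm == pytest.approx(1700.0, rel=0.05)

    def test_psf_lateral_fwhm_interpolates_with_depth(self):
        psf = PSFModel.for_frequency(2.4)
        assert psf.lateral_fwhm_um(30e3) == pytest.approx(1700.0)
        assert psf.lateral_fwhm_um(120e3) == pytest.approx(5850.0)
        assert psf.lateral_fwhm_um(75e3) == pytest.approx((1700 + 5850) / 2)
        psf17 = PSFModel.for_frequency(1.7)
        assert psf17.lateral_fwhm_um(30e3) == pytest.approx(1950.0)
        assert psf17.lateral_fwhm_um(120e3) == pytest.approx(7310.0)


class TestSimulateRF:
    def test_linear_scatterer_cancels_in_am(self, shallow_geom):
        sc = [Scatterer(1e3, 35e3, 1.0, gamma=1.0)]
        full = simulate_rf(sc, shallow_geom, -3.0, "full")
        ha = simulate_rf(sc, shallow_geom, -3.0, "half_a")
        hb = simulate_rf(sc, shallow_geom, -3.0, "half_b")
        residual = full - (ha + hb)
        assert (residual ** 2).sum() < 1e-8 * (full ** 2).sum()

    def test_nonlinear_scatterer_survives_am(self, shallow_geom):
        sc = [Scatterer(1e3, 35e3, 1.0, gamma=1.5)]
        full = simulate_rf(sc, shallow_geom, -3.0, "full")
        ha = simulate_rf(sc, shallow_geom, -3.0, "half_a")
        hb = simulate_rf(sc, shallow_geom, -3.0, "half_b")
        residual = full - (ha + hb)
        assert (residual ** 2).sum() > 1e-3 * (full ** 2).sum()

    def test_centre_element_arrival_matches_two_segment_time_of_flight(self, shallow_geom):
        depth = 30e3
        traces = simulate_rf([Scatterer(0.0, depth, 1.0)], shallow_geom, 0.0, "full")
        fs = 4 * shallow_geom.f_tx_mhz * 1e6
        c_um = shallow_geom.sound_speed_m_s * 1e6
        d = shallow_geom.virtual_source_depth_mm * 1e3
        # analytic: transmit (virtual source to scatterer minus standoff) + return
        t_expected = ((depth + d) - d + math.hypot(
            shallow_geom.element_positions_um[40], depth)) / c_um
        ch = np.abs(traces[40])
        t_peak = np.argmax(ch) / fs
        assert t_peak == pytest.approx(t_expected, abs=1.5 / (shallow_geom.f_tx_mhz * 1e6))
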