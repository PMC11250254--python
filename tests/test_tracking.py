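import itertools

import numpy as np
import pandas as pd
import pytest

from cardioulm.tracking import (FeatureMotionModelTracker, KalmanTrackState,
                                default_measurement_noise,
                                estimate_process_noise, finalize_tracks,
                                fuzzy_init, pair_frame)

FR = 305.0


def make_state(x, z, vx, vz, q_scale=1.0):
    q = np.eye(4) * q_scale
    return KalmanTrackState(state=np.array([x, z, vx, vz]), cov=np.eye(4),
                            q=q, r=default_measurement_noise(), intensity=1.0,
                            track_id=0, history=[(0, x, z, 1.0)])


class TestKalmanPredict:
    def test_constant_velocity_prediction_is_exact(self):
        st = make_state(100.0, 200.0, 3050.0, -6100.0)  # µm/s
        x_pred, _, _ = st.predict(1.0 / FR)
        assert x_pred[0] == pytest.approx(100.0 + 3050.0 / FR)
        assert x_pred[1] == pytest.approx(200.0 - 6100.0 / FR)

    def test_zero_velocity_prediction_stays_put(self):
        st = make_state(10.0, 20.0, 0.0, 0.0)
        x_pred, _, _ = st.predict(0.01)
        assert np.allclose(x_pred[:2], [10.0, 20.0])

    def test_innovation_covariance_grows_with_process_noise(self):
        s_small = make_state(0, 0, 0, 0, q_scale=1.0).predict(0.01)[2]
        s_large = make_state(0, 0, 0, 0, q_scale=100.0).predict(0.01)[2]
        assert np.trace(s_large) > np.trace(s_small)

    def test_update_moves_state_toward_measurement(self):
        st = make_state(0.0, 0.0, 0.0, 0.0)
        x_pred, p_pred, _ = st.predict(0.01)
        st.update(x_pred, p_pred, np.array([50.0, -30.0]))
        assert 0 < st.state[0] <= 50.0
        assert -30.0 <= st.state[1] < 0


def predictions_for(positions, cov_scale=100.0):
    return [(np.asarray(p, float), np.eye(2) * cov_scale) for p in positions]


class TestPairFrame:
    def test_single_track_single_localization_paired(self):
        t_assign, l_assign = pair_frame(
            predictions_for([(0.0, 0.0)]), np.array([[0.0, 0.0]]), np.ones(1),
            np.array([[30.0, 40.0]]), np.ones(1), FR)
        assert t_assign[0] == 0 and l_assign[0] == 0

    def test_displacement_beyond_speed_window_goes_to_dummy(self):
        gate_um = 150.0 / FR * 1e3  # ~492 µm
        t_assign, l_assign = pair_frame(
            predictions_for([(0.0, 0.0)]), np.array([[0.0, 0.0]]), np.ones(1),
            np.array([[gate_um + 50.0, 0.0]]), np.ones(1), FR, max_speed_mm_s=150.0)
        assert t_assign[0] == -1 and l_assign[0] == -1

    def test_crossing_assignment_matches_bruteforce_enumeration(self):
        # two tracks with distinct velocities; enumerate both pairings
        preds = [(np.array([100.0, 100.0]), np.eye(2) * 50.0),
                 (np.array([100.0, 160.0]), np.eye(2) * 50.0)]
        last_pos = np.array([[90.0, 90.0], [90.0, 170.0]])
        last_int = np.array([1.0, 2.0])
        locs = np.array([[105.0, 103.0], [98.0, 155.0]])
        ints = np.array([1.05, 1.9])
        from cardioulm.tracking import _innovation_density, P_FLOOR

        def cost(i, j):
            mis = abs(ints[j] - last_int[i]) / max(ints[j], last_int[i])
            p = _innovation_density(locs[j] - preds[i][0], preds[i][1])
            return mis / max(p, P_FLOOR)

        best = min(itertools.permutations([0, 1]),
                   key=lambda perm: sum(cost(i, perm[i]) for i in range(2)))
        t_assign, _ = pair_frame(preds, last_pos, last_int, locs, ints, FR)
        assert tuple(t_assign) == best

    def test_empty_inputs_give_empty_assignment(self):
        t_assign, l_assign = pair_frame([], np.empty((0, 2)), np.empty(0),
                                        np.empty((0, 2)), np.empty(0), FR)
        assert len(t_assign) == 0 and len(l_assign) == 0

    def test_assignment_is_one_to_one(self, rng):
        n = 12
        preds = predictions_for(rng.uniform(0, 2000, (n, 2)))
        last = np.array([p[0] for p in preds])
        locs = last + rng.uniform(-200, 200, (n, 2))
        t_assign, l_assign = pair_frame(preds, last, np.ones(n), locs,
                                        np.ones(n), FR)
        paired = t_assign[t_assign >= 0]
        assert len(paired) == len(set(paired))


class TestFuzzyInit:
    def test_no_neighbours_gives_zero_velocity(self):
        v = fuzzy_init(np.array([0.0, 0.0]), 1.0, np.empty((0, 2)),
                       np.empty(0), FR)
        assert np.allclose(v, 0.0)

    def test_single_neighbour_gives_displacement_times_rate(self):
        prev = np.array([[100.0, -50.0]])
        v = fuzzy_init(np.array([150.0, -20.0]), 1.0, prev, np.array([1.0]), FR)
        assert np.allclose(v, np.array([50.0, 30.0]) * FR)

    def test_result_inside_convex_hull_of_candidate_velocities(self, rng):
        new = np.array([0.0, 0.0])
        prev = rng.uniform(-300, 300, (6, 2))
        ints = rng.uniform(0.5, 2.0, 6)
        v = fuzzy_init(new, 1.0, prev, ints, FR)
        cands = (new[None, :] - prev) * FR
        # weighted mean with positive weights stays inside the bounding box
        assert cands[:, 0].min() - 1e-9 <= v[0] <= cands[:, 0].max() + 1e-9
        assert cands[:, 1].min() - 1e-9 <= v[1] <= cands[:, 1].max() + 1e-9


class TestProcessNoise:
    def test_constant_velocity_tracks_give_negligible_q(self):
        tracks = []
        for k in range(5):
            t = np.arange(50) / FR
            pos = np.column_stack([1000 * k + 20e3 * t, 500 * k - 10e3 * t])
            tracks.append(pos)
        q = estimate_process_noise(tracks, FR)
        meas_var = default_measurement_noise()[0, 0]
        assert q[2, 2] < 1e-3 * meas_var * FR ** 2

    def test_white_acceleration_variance_recovered(self, rng):
        sigma_a = 2000.0  # µm/s per frame step
        tracks = []
        for k in range(10):
            n = 1000
            dv = rng.normal(0, sigma_a, (n, 2))
            v = np.cumsum(dv, axis=0)
            pos = np.cumsum(v / FR, axis=0)
            tracks.append(pos)
        q = estimate_process_noise(tracks, FR)
        assert np.sqrt(q[2, 2]) == pytest.approx(sigma_a, rel=0.2)
        assert np.sqrt(q[3, 3]) == pytest.approx(sigma_a, rel=0.2)

    def test_empty_input_returns_documented_default(self):
        q = estimate_process_noise([], FR)
        from cardioulm.tracking import DEFAULT_SIGMA_V_MM_S
        assert q[2, 2] == pytest.approx((DEFAULT_SIGMA_V_MM_S * 1e3) ** 2)


class TestFinalize:
    def test_length_filter_keeps_at_least_four_frames(self):
        hists = [[(f, 10.0 * f, 0.0, 1.0) for f in range(n)] for n in (2, 3, 4, 5)]
        ts = finalize_tracks(hists, FR, min_frames=4)
        lengths = sorted(ts.data.groupby("track_id").size())
        assert lengths == [4, 5]

    def test_min_frames_one_keeps_everything(self):
        hists = [[(0, 0.0, 0.0, 1.0)], [(0, 5.0, 5.0, 1.0), (1, 6.0, 5.0, 1.0)]]
        ts = finalize_tracks(hists, FR, min_frames=1)
        assert ts.n_tracks == 2

    def test_empty_set_stays_empty(self):
        assert finalize_tracks([], FR).n_tracks == 0

    def test_per_step_velocity_is_displacement_times_rate(self):
        hist = [(f, 100.0 * f, -50.0 * f, 1.0) for f in range(5)]
        ts = finalize_tracks([hist], FR, min_frames=4)
        t = ts.track(0)
        assert np.allclose(t["vx_mm_s"], 100.0 * FR * 1e-3)
        assert np.allclose(t["vz_mm_s"], -50.0 * FR * 1e-3)


def constant_velocity_scene(rng, n_bubbles=15, n_frames=25, noise_um=5.0):
    rows = []
    for b in range(n_bubbles):
        p = rng.uniform(0, 30000, 2)
        v = rng.uniform(-40, 40, 2)  # mm/s
        inten = rng.uniform(0.5, 2.0)
        for f in range(n_frames):
            rows.append((f,
                         p[0] + v[0] * 1e3 * f / FR + rng.normal(0, noise_um),
                         p[1] + v[1] * 1e3 * f / FR + rng.normal(0, noise_um),
                         inten * (1 + rng.normal(0, 0.05)), b))
    return pd.DataFrame(rows, columns=["frame", "x_um", "z_um", "intensity",
                                       "true_id"])


def crossing_scene(rng, n_pairs=8, n_frames=25):
    rows = []
    for k in range(n_pairs):
        c = rng.uniform(0, 40000, 2)
        v1 = np.array([30.0, 12.0]) + rng.normal(0, 2, 2)
        v2 = np.array([30.0, -12.0]) + rng.normal(0, 2, 2)
        for f in range(n_frames):
            dt = (f - n_frames / 2) / FR * 1e3
            rows.append((f, c[0] + v1[0] * dt, c[1] + v1[1] * dt, 1.0, 2 * k))
            rows.append((f, c[0] + v2[0] * dt, c[1] + v2[1] * dt, 1.0, 2 * k + 1))
    return pd.DataFrame(rows, columns=["frame", "x_um", "z_um", "intensity",
                                       "true_id"])


def pairing_stats(ts, df):
    key = {(r.frame, round(r.x_um, 4), round(r.z_um, 4)): r.true_id
           for r in df.itertuples()}
    correct = total = 0
    for tid in ts.track_ids():
        t = ts.track(tid)
        ids = [key[(r.frame, round(r.x_um, 4), round(r.z_um, 4))]
               for r in t.itertuples()]
        for a, b in zip(ids[:-1], ids[1:]):
            total += 1
            correct += (a == b)
    return correct, total


class TestEndToEndTracking:
    def test_identity_accuracy_at_least_95_percent(self, rng):
        df = constant_velocity_scene(rng)
        ts = FeatureMotionModelTracker(FR).track(
            df[["frame", "x_um", "z_um", "intensity"]])
        correct, total = pairing_stats(ts, df)
        assert total > 0
        assert correct / total >= 0.95

    def test_motion_model_beats_nearest_neighbour_on_crossings(self, rng):
        sw_fmm = sw_nn = 0
        for seed in range(3):
            df = crossing_scene(np.random.default_rng(seed))
            locs = df[["frame", "x_um", "z_um", "intensity"]]
            c_f, t_f = pairing_stats(FeatureMotionModelTracker(FR, mode="fmm").track(locs), df)
            c_n, t_n = pairing_stats(FeatureMotionModelTracker(FR, mode="nn").track(locs), df)
            sw_fmm += t_f - c_f
            sw_nn += t_n - c_n
        assert sw_fmm < sw_nn  # strictly fewer identity switches

    def test_mean_track_speed_within_10_percent(self, rng):
        speed = 25.0
        rows = []
        for b in range(8):
            p = np.array([5000.0 * b, 10000.0])
            for f in range(20):
                rows.append((f, p[0], p[1] + speed * 1e3 * f / FR, 1.0))
        df = pd.DataFrame(rows, columns=["frame", "x_um", "z_um", "intensity"])
        ts = FeatureMotionModelTracker(FR).track(df)
        for tid in ts.track_ids():
            t = ts.track(tid)
            mean_speed = np.hypot(t["vx_mm_s"], t["vz_mm_s"]).mean()
            assert mean_speed == pytest.approx(speed, rel=0.10)

    def test_each_localization_used_at_most_once(self, rng):
        df = constant_velocity_scene(rng, n_bubbles=10)
        ts = FeatureMotionModelTracker(FR).track(
            df[["frame", "x_um", "z_um", "intensity"]])
        seen = set()
        for r in ts.data.itertuples():
            k = (r.frame, r.x_um, r.z_um)
            assert k not in seen
            seen.add(k)

    def test_frames_strictly_increasing_within_tracks(self, rng):
        df = constant_velocity_scene(rng, n_bubbles=10)
        ts = FeatureMotionModelTracker(FR).track(
            df[["frame", "x_um", "z_um", "intensity"]])
        for tid in ts.track_ids():
            assert (np.diff(ts.track(tid)["frame"]) > 0).all()
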