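"""Kalman filter, Hungarian association, track lifecycle, tracking rate."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermtrack.count import Detection
from spermtrack.datasets import load_tracking_benchmark
from spermtrack.synthetic import simulate_video, well_separated_scene
from spermtrack.tracking import (A_CV, H_POS, KalmanState, Tracker, TrackerParams, TrackScore,
                                 assign, kalman_predict, kalman_update, match_tracks_to_truth,
                                 summarize_tracking, track_video, tracking_rate)


def det(r, c, frame=0, area=25):
    rr, cc = int(r), int(c)
    return Detection(frame_index=frame, centroid=(float(r), float(c)), area=area,
                     bbox=(rr - 2, cc - 2, rr + 3, cc + 3))


class TestKalmanPredict:
    def test_constant_velocity_propagation(self):
        s = KalmanState([0, 0, 1, 2], np.zeros((4, 4)))
        out = kalman_predict(s)
        assert np.allclose(out.x, [1, 2, 1, 2])
        assert np.allclose(out.P, 0)

    def test_covariance_matches_direct_matrix_arithmetic(self, rng):
        M = rng.normal(size=(4, 4))
        P = M @ M.T  # random PSD
        Q = 0.01 * np.eye(4)
        s = KalmanState(rng.normal(size=4), P)
        out = kalman_predict(s, A_CV, Q)
        assert np.allclose(out.P, A_CV @ P @ A_CV.T + Q)
        assert np.allclose(out.x, A_CV @ s.x)


class TestKalmanUpdate:
    def test_scalar_analog_half_gain(self):
        # 1-D analogue: P⁻=1, R=1, H=1, x̂⁻=0, z=2 ⇒ K=0.5, x̂=1, P=0.5.
        # Embedded in the (row, col) observation with the col/velocity parts inert.
        P = np.diag([1.0, 0.0, 0.0, 0.0])
        s = kalman_update(KalmanState([0, 0, 0, 0], P), [2.0, 0.0], H_POS, np.eye(2))
        assert s.x[0] == pytest.approx(1.0)
        assert s.P[0, 0] == pytest.approx(0.5)

    def test_zero_measurement_noise_snaps_to_measurement(self):
        s = KalmanState([5.0, 5.0, 1.0, 1.0], np.eye(4))
        out = kalman_update(s, [8.0, 2.0], H_POS, 1e-12 * np.eye(2))
        assert np.allclose(out.x[:2], [8.0, 2.0], atol=1e-6)

    def test_zero_prior_covariance_ignores_measurement(self):
        s = KalmanState([5.0, 5.0, 1.0, 1.0], np.zeros((4, 4)))
        out = kalman_update(s, [100.0, 100.0], H_POS, np.eye(2))
        assert np.allclose(out.x, s.x)

    def test_singular_innovation_raises(self):
        s = KalmanState([0, 0, 0, 0], np.zeros((4, 4)))
        with pytest.raises(np.linalg.LinAlgError):
            kalman_update(s, [1.0, 1.0], H_POS, np.zeros((2, 2)))

    def test_matches_direct_matrix_arithmetic_on_random_psd(self, rng):
        for _ in range(25):
            M = rng.normal(size=(4, 4))
            P = M @ M.T + 1e-6 * np.eye(4)
            R = np.diag(rng.uniform(0.1, 2.0, 2))
            x = rng.normal(size=4)
            z = rng.normal(size=2)
            out = kalman_update(KalmanState(x, P), z, H_POS, R)
            K = P @ H_POS.T @ np.linalg.inv(H_POS @ P @ H_POS.T + R)
            assert np.allclose(out.x, x + K @ (z - H_POS @ x))
            assert np.allclose(out.P, (np.eye(4) - K @ H_POS) @ P, atol=1e-9)

    def test_covariance_stays_psd_through_cycles(self, rng):
        s = KalmanState(rng.normal(size=4), np.diag([1, 1, 10, 10.0]))
        for _ in range(50):
            s = kalman_predict(s, A_CV, 0.01 * np.eye(4))
            s = kalman_update(s, rng.normal(size=2), H_POS, np.eye(2))
            assert np.linalg.eigvalsh(s.P).min() >= -1e-9


class TestAssign:
    def test_diagonal_dominant_identity_matching(self):
        pts = [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0)]
        matches, ut, ud = assign(pts, pts, gate=5.0)
        assert sorted(matches) == [(0, 0), (1, 1), (2, 2)]
        assert ut == ud == []

    def test_no_detections_all_unmatched(self):
        matches, ut, ud = assign([(0.0, 0.0)], [], gate=5.0)
        assert matches == [] and ut == [0] and ud == []

    def test_gate_demotes_far_pairs(self):
        matches, ut, ud = assign([(0.0, 0.0)], [(100.0, 100.0)], gate=5.0)
        assert matches == [] and ut == [0] and ud == [0]

    def test_total_cost_equals_bruteforce_permutation_minimum(self, rng):
        for n in range(2, 7):
            for _ in range(10):
                a = rng.uniform(0, 100, size=(n, 2))
                b = rng.uniform(0, 100, size=(n, 2))
                matches, _, _ = assign(a, b, gate=1e9)
                cost = sum(np.linalg.norm(a[i] - b[j]) for i, j in matches)
                brute = min(sum(np.linalg.norm(a[i] - b[p[i]]) for i in range(n))
                            for p in itertools.permutations(range(n)))
                assert cost == pytest.approx(brute)


class TestTrackerLifecycle:
    def test_match_extends_track(self):
        tr = Tracker(TrackerParams())
        tr.step([det(10, 10, 0)], 0)
        tr.step([det(11, 11, 1)], 1)
        (t,) = tr.tracks
        assert t.frames_tracked == 2 and t.misses == 0

    def test_track_deleted_after_max_age_misses(self):
        tr = Tracker(TrackerParams(max_age=3))
        tr.step([det(10, 10, 0)], 0)
        for f in range(1, 5):
            tr.step([], f)
        assert tr.tracks[0].status == "deleted"

    def test_ids_monotone_and_never_reused(self):
        tr = Tracker(TrackerParams(max_age=0, gate=5.0))
        tr.step([det(10, 10)], 0)
        tr.step([], 1)              # track 1 deleted
        tr.step([det(200, 200)], 2)  # far away: must be a fresh id
        assert [t.id for t in tr.tracks] == [1, 2]

    def test_exact_constant_velocity_prediction_with_zero_noise(self):
        # vanishing (not exactly zero) R keeps the innovation invertible
        p = TrackerParams(process_noise=0.0, measurement_noise=1e-9, gate=50.0)
        tr = Tracker(p)
        for f in range(6):
            tr.step([det(10.0 + 3 * f, 20.0 + 4 * f, f)], f)
            if f >= 2:
                # after two updates the velocity is locked in: prediction == next detection
                from spermtrack.tracking import kalman_predict as kp

                pred = kp(tr.tracks[0].kalman, A_CV, p.Q)
                assert np.allclose(pred.x[:2], [10.0 + 3 * (f + 1), 20.0 + 4 * (f + 1)], atol=1e-6)


class TestTrackVideo:
    def test_blank_video_gives_no_tracks(self, desk_calibration):
        from spermtrack.io import FrameSequence

        frames = np.full((10, 64, 64), 60, dtype=np.uint8)
        assert track_video(FrameSequence(frames, desk_calibration)) == []

    def test_single_swimmer_single_full_track(self):
        from spermtrack.synthetic import single_swimmer_scene

        seq, truth = simulate_video(single_swimmer_scene(25.0, noise_sigma=0.0, seed=2))
        tracks = track_video(seq)
        assert len(tracks) == 1
        assert tracks[0].frames_tracked == 90

    def test_deterministic_given_seeded_scene(self):
        seq, _ = simulate_video(well_separated_scene(seed=3))
        a = track_video(seq)
        b = track_video(seq)
        assert [(t.id, t.centroids) for t in a] == [(t.id, t.centroids) for t in b]

    def test_well_separated_scene_fully_tracked(self, well_separated):
        seq, truth = well_separated
        scores = match_tracks_to_truth(track_video(seq), truth.centroids_px(motile_only=True))
        assert len(scores) == len(truth.sperm_objects(motile_only=True))
        assert all(s.rt == 100.0 for s in scores)


class TestTrackingRate:
    @pytest.mark.parametrize("ft,fw,expected", [(55, 90, 61.11), (72, 72, 100.0), (11, 62, 17.74)])
    def test_benchmark_pairs(self, ft, fw, expected):
        assert tracking_rate(ft, fw) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tracking_rate(1, 0)
        with pytest.raises(ValueError):
            tracking_rate(5, 3)

    @given(st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_bounded_between_0_and_100(self, ft, fw):
        ft = min(ft, fw)
        assert 0.0 <= tracking_rate(ft, fw) <= 100.0

    def test_summary_of_single_perfect_score(self):
        s = summarize_tracking([TrackScore(ft=10, fw=10)])
        assert s == {"mean_rate": 100.0, "frac_100": 100.0, "frac_below_50": 0.0}

    def test_summary_of_benchmark_table(self):
        df = load_tracking_benchmark()
        s = summarize_tracking(list(df["rt"]))
        assert round(s["mean_rate"]) == 86
        assert s["frac_100"] == 70.59
        assert s["frac_below_50"] == 5.88

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            summarize_tracking([])
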