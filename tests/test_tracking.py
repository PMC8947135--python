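import numpy as np
import pytest

from clutterflight.tracking import (COASTED, MEASURED, Detection2D,
                                    KalmanConfig, NoTrackError,
                                    brute_force_assign, detect_blobs,
                                    estimate_background, kalman_step,
                                    munkres_assign, track_single_target)


def det(frame, u, v, area=25.0, cam="cam_a"):
    return Detection2D(camera_id=cam, frame_index=frame, centroid=(u, v),
                       area=area)


class TestBackground:
    def test_constant_stack(self):
        stack = np.full((5, 10, 10), 37.0)
        assert np.array_equal(estimate_background(stack), stack[0])

    def test_outlier_frame_ignored(self, rng):
        base = rng.uniform(0, 100, (10, 10))
        stack = np.repeat(base[None], 11, axis=0)
        stack[4] += 200.0
        assert np.allclose(estimate_background(stack), base)

    def test_moving_blob_removed(self, rng):
        texture = rng.uniform(40, 120, (40, 60))
        frames = []
        for i in range(15):
            img = texture.copy()
            yy, xx = np.mgrid[0:40, 0:60]
            img += 150 * np.exp(-((xx - 4 * i) ** 2 + (yy - 20) ** 2) / 8.0)
            frames.append(img)
        bg = estimate_background(frames)
        assert np.max(np.abs(bg - texture)) < 30.0  # below blob threshold

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((2, 5, 5)))


class TestDetectBlobs:
    def test_no_difference_no_blobs(self):
        img = np.full((30, 30), 50.0)
        assert detect_blobs(img, img, threshold=10) == []

    def test_gaussian_blob_subpixel_centroid(self):
        bg = np.full((100, 200), 50.0)
        yy, xx = np.mgrid[0:100, 0:200]
        truth = (120.3, 45.7)
        frame = bg + 150 * np.exp(-((xx - truth[0]) ** 2 + (yy - truth[1]) ** 2)
                                  / (2 * 2.0 ** 2))
        (d,) = detect_blobs(frame, bg, threshold=15, min_blob_area=4)
        assert np.hypot(d.centroid[0] - truth[0], d.centroid[1] - truth[1]) < 0.5

    def test_two_blobs_sorted_by_area(self):
        bg = np.zeros((60, 60))
        frame = bg.copy()
        frame[5:9, 5:9] = 100.0  # 16 px
        frame[40:50, 40:50] = 100.0  # 100 px
        blobs = detect_blobs(frame, bg, threshold=50, min_blob_area=4)
        assert len(blobs) == 2
        assert blobs[0].area > blobs[1].area
        assert blobs[0].centroid[0] > 30  # the big one

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            detect_blobs(np.zeros((10, 10)), np.zeros((9, 10)), 1)


class TestMunkres:
    def test_diagonal_optimum(self):
        cost = np.ones((3, 3)) - np.eye(3)
        assert munkres_assign(cost) == {0: 0, 1: 1, 2: 2}

    @pytest.mark.parametrize("seed", range(10))
    def test_square_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cost = rng.integers(0, 50, (4, 4)).astype(float)
        a = munkres_assign(cost)
        total = sum(cost[r, c] for r, c in a.items())
        assert total == pytest.approx(brute_force_assign(cost))

    def test_rectangular_matches_brute_force(self, rng):
        cost = rng.uniform(0, 10, (2, 3))
        a = munkres_assign(cost)
        assert len(a) == 2
        total = sum(cost[r, c] for r, c in a.items())
        assert total == pytest.approx(brute_force_assign(cost))

    def test_never_beaten_by_random_permutation(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 6))
            cost = rng.uniform(0, 10, (n, n))
            a = munkres_assign(cost)
            total = sum(cost[r, c] for r, c in a.items())
            perm = rng.permutation(n)
            assert total <= sum(cost[i, perm[i]] for i in range(n)) + 1e-12

    def test_empty(self):
        assert munkres_assign(np.zeros((0, 0))) == {}


class TestTracker:
    config = KalmanConfig()

    def straight_detections(self, n=40, missing=()):
        return {f: ([] if f in missing else [det(f, 100 + 2.0 * f, 50 + 1.0 * f)])
                for f in range(n)}

    def test_clean_path_follows_detections(self):
        track = track_single_target(self.straight_detections(), self.config)
        assert len(track) == 40
        expected_u = 100 + 2.0 * track.frames
        # sub-millipixel agreement once the velocity estimate has converged
        assert np.allclose(track.states[:, 0], expected_u, atol=5e-3)
        assert np.allclose(track.states[10:, 0], expected_u[10:], atol=1e-6)
        # velocities converge to the per-frame displacement
        assert np.allclose(track.states[10:, 2], 2.0, atol=1e-4)
        assert all(f == MEASURED for f in track.flags)

    def test_gap_is_coasted_with_linear_prediction(self):
        track = track_single_target(self.straight_detections(missing={20}),
                                    self.config)
        i = 20 - track.start_frame
        assert track.flags[i] == COASTED
        prev = track.states[i - 1]
        assert track.states[i][0] == pytest.approx(prev[0] + prev[2])
        assert track.states[i][1] == pytest.approx(prev[1] + prev[3])

    def test_kalman_step_matches_hand_computation(self):
        """One predict/update cycle against the textbook formulas."""
        cfg = KalmanConfig(process_noise_accel=1.0, measurement_noise=0.7)
        state = np.array([10.0, 20.0, 1.0, -1.0])
        P = np.diag([1.0, 1.0, 4.0, 4.0])
        z = np.array([11.5, 18.9])
        F = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]],
                     dtype=float)
        G = np.array([[0.5, 0], [0, 0.5], [1, 0], [0, 1]])
        Q = G @ G.T
        H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        R = 0.49 * np.eye(2)
        xp = F @ state
        Pp = F @ P @ F.T + Q
        K = Pp @ H.T @ np.linalg.inv(H @ Pp @ H.T + R)
        x_hand = xp + K @ (z - H @ xp)
        P_hand = (np.eye(4) - K @ H) @ Pp
        x_got, P_got, pred = kalman_step(state, P, z, cfg)
        assert np.allclose(x_got, x_hand)
        assert np.allclose(P_got, P_hand)
        assert np.allclose(pred, xp[:2])

    def test_distractor_outside_gate_ignored(self):
        base = self.straight_detections()
        with_distractor = {
            f: dets + [det(f, 100 + 2.0 * f + 3 * self.config.gate_radius,
                           50 + 1.0 * f, area=9.0)]
            for f, dets in base.items()}
        t0 = track_single_target(base, self.config)
        t1 = track_single_target(with_distractor, self.config)
        assert np.allclose(t0.states, t1.states)

    def test_track_has_no_gaps(self):
        track = track_single_target(
            self.straight_detections(missing={10, 11, 25}), self.config)
        assert len(track.frames) == len(track.states) == len(track.flags)
        assert np.array_equal(np.diff(track.frames), np.ones(len(track) - 1))

    def test_no_track_error(self):
        with pytest.raises(NoTrackError):
            track_single_target({0: [det(0, 10, 10)]}, self.config)
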