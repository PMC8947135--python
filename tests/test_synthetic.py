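import numpy as np
import pytest

from clutterflight.kinematics import ROUTE_ABOVE, ROUTE_WITHIN, TrialCondition
from clutterflight.scene import build_scene
from clutterflight.synthetic import (BehaviorConfig, observe_flight,
                                     render_frames, simulate_experiment,
                                     simulate_flight)
from clutterflight.tracking import detect_blobs, estimate_background


def flights_at(height, n, seed=0, **cfg_kwargs):
    cfg = BehaviorConfig(seed=seed, **cfg_kwargs)
    scene = build_scene(height)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cond = TrialCondition("bee000", i + 1, "still", "up_tunnel", float(height))
        out.append(simulate_flight(cond, cfg, scene, rng))
    return out


class TestConfig:
    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            BehaviorConfig(p_within=((11.0, 0.0), (127.0, 1.5)))

    def test_control_field_must_exclude_within(self):
        with pytest.raises(ValueError):
            BehaviorConfig(p_within=((11.0, 0.2), (127.0, 0.5)))


class TestSimulateFlight:
    def test_control_field_always_above(self):
        assert all(f.route == ROUTE_ABOVE for f in flights_at(11, 50))

    def test_within_fraction_matches_configured_probability(self):
        flights = flights_at(127, 600, seed=4)
        frac = np.mean([f.route == ROUTE_WITHIN for f in flights])
        assert 0.50 <= frac <= 0.60  # p = 0.55, binomial at n = 600

    def test_route_constraints_respected(self):
        for f in flights_at(127, 40, seed=5):
            z = f.positions[f.in_field, 2]
            y = f.positions[f.in_field, 1]
            if f.route == ROUTE_ABOVE:
                assert z.min() > 127.0
            else:
                assert np.median(z) <= 127.0
                # within-route flights stay inside one 57-mm corridor
                assert (np.all(np.abs(y - 32) < 28.5)
                        or np.all(np.abs(y + 32) < 28.5))

    def test_positions_respect_tunnel_bounds(self):
        for f in flights_at(98, 30, seed=6):
            assert np.all(np.abs(f.positions[:, 1]) <= 100.0)
            assert np.all(f.positions[:, 2] >= 0)
            assert np.all(f.positions[f.in_field, 2] <= 191.0)

    def test_true_metrics_match_generated_path(self):
        for f in flights_at(69, 10, seed=7):
            m = f.in_field
            speed = np.hypot(f.velocities[m, 0], f.velocities[m, 1])
            assert np.median(speed) == pytest.approx(
                f.true_metrics["ground_speed"], rel=1e-9)
            assert np.ptp(f.positions[m, 2]) == pytest.approx(
                f.true_metrics["altitude_range"], rel=1e-9)

    def test_still_air_median_speed_calibrated(self):
        """Median over still-air flights (both routes pooled) approaches
        the configured 0.32 m/s."""
        exp = simulate_experiment(BehaviorConfig(n_bees=56, seed=8),
                                  observe=False)
        tt = exp.truth_table()
        med = tt[tt.wind == "still"].ground_speed.median() / 1000.0
        assert med == pytest.approx(0.32, rel=0.03)


class TestObserveFlight:
    def test_noiseless_matches_projection(self, rig):
        from clutterflight.camera import project_many
        (flight,) = flights_at(69, 1, seed=9)
        obs = observe_flight(flight, rig, noise=0.0, dropout=0.0,
                             rng=np.random.default_rng(0))
        uv = project_many(rig[0], flight.positions)
        for i, dets in obs[rig[0].camera_id].items():
            assert dets[0].centroid == pytest.approx(tuple(uv[i]), abs=1e-9)

    def test_dropout_binomial_band(self, rig):
        (flight,) = flights_at(69, 1, seed=10)
        n = len(flight.times)
        obs = observe_flight(flight, rig, noise=0.0, dropout=0.05,
                             rng=np.random.default_rng(1))
        missing = n - len(obs[rig[0].camera_id])
        sd = np.sqrt(n * 0.05 * 0.95)
        assert abs(missing - 0.05 * n) < 2.58 * sd  # 99% band

    def test_distractors_flagged(self, rig):
        (flight,) = flights_at(69, 1, seed=11)
        obs = observe_flight(flight, rig, noise=0.0, dropout=0.0,
                             distractor_rate=0.2, rng=np.random.default_rng(2))
        flags = [d.is_distractor for dets in obs[rig[0].camera_id].values()
                 for d in dets]
        assert any(flags) and not all(flags)


class TestRenderFrames:
    def test_detection_round_trip(self, rig):
        (flight,) = flights_at(69, 1, seed=12)
        frames, bg, centroids = render_frames(flight, rig[0], texture_seed=3)
        errs = []
        for img, (u, v) in zip(frames, centroids):
            dets = detect_blobs(img, bg, threshold=45, min_blob_area=4)
            assert dets, "blob not detected"
            errs.append(np.hypot(dets[0].centroid[0] - u,
                                 dets[0].centroid[1] - v))
        assert np.sqrt(np.mean(np.square(errs))) < 0.5

    def test_background_recovered_by_median(self, rig):
        (flight,) = flights_at(69, 1, seed=13)
        frames, bg, _ = render_frames(flight, rig[0], texture_seed=4)
        est = estimate_background(frames)
        assert np.max(np.abs(est - bg)) < 45.0  # below the blob threshold

    def test_absent_blob_yields_no_detection(self, rig):
        (flight,) = flights_at(69, 1, seed=14)
        _, bg, _ = render_frames(flight, rig[0], texture_seed=5)
        assert detect_blobs(bg, bg, threshold=45) == []


class TestSimulateExperiment:
    def test_seeded_determinism(self):
        cfg = BehaviorConfig(n_bees=4, seed=21)
        t1 = simulate_experiment(cfg, observe=False).truth_table()
        t2 = simulate_experiment(cfg, observe=False).truth_table()
        assert t1.equals(t2)

    def test_flight_counts_in_design_range(self, small_experiment):
        tt = small_experiment.truth_table()
        per_bee = tt.groupby("bee_id").size()
        assert per_bee.between(5, 13).all()
        assert len(tt) == per_bee.sum()

    def test_one_field_height_per_bee(self, small_experiment):
        tt = small_experiment.truth_table()
        assert (tt.groupby("bee_id").field_height.nunique() == 1).all()

    def test_both_wind_conditions_and_directions_present(self, small_experiment):
        tt = small_experiment.truth_table()
        per_bee = tt.groupby("bee_id").wind.nunique()
        assert (per_bee == 2).all()
        assert set(tt.direction) == {"up_tunnel", "down_tunnel"}
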