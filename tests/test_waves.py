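import numpy as np
import pytest

from voltwave import synth, waves

RATE = 300.0
PITCH = 0.05


def make_wave_movie(speed, direction, freq, shape=(600, 64, 64),
                    noise_sd=0.0, seed=1, envelope=(0.0, 2.0)):
    movie, truth = synth.gen_movie(
        synth.PlaneWaveSpec(speed_mm_s=speed, direction_deg=direction,
                            freq_hz=freq, envelope=envelope),
        artifact=synth.quiet_artifact(), shape=shape, rate_hz=RATE,
        pixel_pitch_mm=PITCH, noise_sd=noise_sd, seed=seed)
    return movie, truth


class TestSeedDelayMap:
    def test_noise_free_plane_wave_gives_linear_delays(self):
        movie, _ = make_wave_movie(220.0, 0.0, 20.0)
        dm = waves.seed_delay_map(movie.gevi, RATE, PITCH, (32, 32),
                                  max_lag_s=0.02)
        row = dm.delay_s[32]
        x_mm = np.arange(64) * PITCH
        coef = np.polyfit(x_mm, row, 1)
        resid = row - np.polyval(coef, x_mm)
        r2 = 1 - resid.var() / row.var()
        assert r2 > 0.999
        assert coef[0] == pytest.approx(1 / 220.0, rel=0.02)

    def test_seed_pixel_has_unit_correlation_zero_delay(self):
        movie, _ = make_wave_movie(100.0, 45.0, 15.0)
        dm = waves.seed_delay_map(movie.gevi, RATE, PITCH, (32, 32),
                                  max_lag_s=0.03)
        assert dm.corr[32, 32] == pytest.approx(1.0, abs=1e-9)
        assert dm.delay_s[32, 32] == 0.0

    def test_uncorrelated_noise_movie_mostly_invalid(self):
        rng = np.random.default_rng(9)
        v = rng.standard_normal((600, 16, 16))
        dm = waves.seed_delay_map(v, RATE, PITCH, (8, 8), max_lag_s=0.05,
                                  xmin=0.6)
        frac_valid = dm.valid_mask.mean()
        assert frac_valid < 0.02


class TestPlaneFit:
    def test_speed_and_direction_recovered(self):
        movie, _ = make_wave_movie(220.0, 0.0, 20.0)
        dm = waves.seed_delay_map(movie.gevi, RATE, PITCH, (32, 32),
                                  max_lag_s=0.02)
        ev = waves.fit_plane_velocity(dm, xmin=0.7)
        assert ev.accepted
        assert ev.speed_mm_s == pytest.approx(220.0, rel=0.02)
        assert abs((ev.direction_deg + 180) % 360 - 180) < 2.0

    def test_oblique_wave_has_equal_wavenumbers(self):
        movie, _ = make_wave_movie(100.0, 45.0, 15.0)
        dm = waves.seed_delay_map(movie.gevi, RATE, PITCH, (32, 32),
                                  max_lag_s=0.03)
        ev = waves.fit_plane_velocity(dm, xmin=0.7)
        assert ev.alpha_x / ev.alpha_y == pytest.approx(1.0, rel=0.05)

    def test_synchronous_oscillation_rejected(self):
        t = np.arange(600) / RATE
        v = np.cos(2 * np.pi * 10 * t)[:, None, None] * np.ones((1, 16, 16))
        dm = waves.seed_delay_map(v, RATE, PITCH, (8, 8), max_lag_s=0.03)
        ev = waves.fit_plane_velocity(dm, xmin=0.7)
        assert not ev.accepted
        assert ev.reject_reason == "synchronous"

    def test_literal_formula_reports_component_inverses(self):
        movie, _ = make_wave_movie(100.0, 45.0, 15.0)
        dm = waves.seed_delay_map(movie.gevi, RATE, PITCH, (32, 32),
                                  max_lag_s=0.03)
        ev = waves.fit_plane_velocity(dm, xmin=0.7, literal_formula=True)
        assert ev.velocity_mm_s[0] == pytest.approx(1 / ev.alpha_x)
        assert ev.velocity_mm_s[1] == pytest.approx(1 / ev.alpha_y)


class TestPairwise:
    def test_two_pixel_arithmetic(self):
        dmap = waves.DelayMap(
            corr=np.ones((1, 2)), delay_s=np.array([[0.0, 0.005]]),
            seed_yx=(0, 0), pixel_pitch_mm=1.0)
        speeds, dirs = waves.pairwise_velocities(dmap, xmin=0.5)
        assert speeds[0] == pytest.approx(200.0)
        assert dirs[0] == pytest.approx(0.0)

    def test_median_pairwise_speed_near_truth(self):
        # points sampled along the propagation axis, where the pairwise
        # distance/delay ratio is the true phase speed
        movie, _ = make_wave_movie(100.0, 0.0, 15.0, shape=(600, 16, 16))
        dm = waves.seed_delay_map(movie.gevi, RATE, PITCH, (8, 8),
                                  max_lag_s=0.03)
        pts = [(8, x) for x in range(0, 16, 2)]
        speeds, dirs = waves.pairwise_velocities(
            dm, xmin=0.7, point_set=pts, min_delay_s=1.0 / RATE)
        assert len(speeds) > 0
        assert np.median(speeds) == pytest.approx(100.0, rel=0.10)
        assert np.abs((dirs + 180) % 360 - 180).max() < 1.0

    def test_subthreshold_pairs_excluded(self):
        dmap = waves.DelayMap(
            corr=np.array([[1.0, 0.2]]), delay_s=np.array([[0.0, 0.005]]),
            seed_yx=(0, 0), pixel_pitch_mm=1.0)
        speeds, _ = waves.pairwise_velocities(dmap, xmin=0.5,
                                              point_set=[(0, 0), (0, 1)])
        assert len(speeds) == 0


class TestWaveEventDetection:
    def test_quiescent_movie_has_no_events(self, rng):
        v = 0.01 * rng.standard_normal((3000, 8, 8))
        # gaussian noise: mean trace stays within 3 sd nearly surely after
        # spatial averaging? use a strict threshold to make it robust
        windows = waves.detect_wave_events(v, RATE, threshold_sd=6.0)
        assert windows == []

    def test_injected_bouts_found(self, rng):
        # sparse bouts (1.5% duty cycle) so the global standard deviation
        # stays noise-dominated and the 3-sd gate catches every bout
        nt = 18000
        base = 0.05 * rng.standard_normal((nt, 8, 8))
        t = np.arange(nt) / RATE
        for k in range(10):
            onset = 1.0 + 5.8 * k
            sel = (t >= onset) & (t < onset + 0.1)
            base[sel] += 2.0 * np.sin(
                2 * np.pi * 10 * (t[sel] - onset))[:, None, None]
        windows = waves.detect_wave_events(base, RATE, threshold_sd=3.0)
        starts = np.array([w[0] for w in windows])
        expected = 1.0 + 5.8 * np.arange(10)
        hits = sum(np.abs(starts - e).min() < 0.3 for e in expected)
        assert hits == 10

    def test_zero_threshold_spans_recording(self, rng):
        v = rng.standard_normal((600, 4, 4))
        windows = waves.detect_wave_events(v, RATE, threshold_sd=0.0)
        assert windows[0][0] == 0.0
        assert windows[-1][1] == pytest.approx(600 / RATE)


class TestProjection:
    def test_plane_wave_projections(self):
        movie, _ = make_wave_movie(100.0, 0.0, 15.0, shape=(300, 32, 32))
        px, pos = waves.spacetime_project(movie.gevi, "x", PITCH)
        py, _ = waves.spacetime_project(movie.gevi, "y", PITCH)
        assert px.shape == (300, 32)
        # wave along +x: the y-projection is spatially uniform
        assert np.abs(py - py.mean(axis=1, keepdims=True)).max() < 1e-9
        assert np.ptp(px, axis=1).max() > 0.1
        assert pos[1] - pos[0] == pytest.approx(PITCH)

    def test_projection_preserves_global_mean(self, rng):
        v = rng.standard_normal((100, 8, 12))
        px, _ = waves.spacetime_project(v, "x", PITCH)
        assert px.mean() == pytest.approx(v.mean(), abs=1e-12)


class TestWavenumberRegression:
    def test_oblique_wave_accepted_with_both_axes_significant(self):
        movie, _ = make_wave_movie(100.0, 45.0, 15.0)
        px, _ = waves.spacetime_project(movie.gevi, "x", PITCH)
        py, _ = waves.spacetime_project(movie.gevi, "y", PITCH)
        ev = waves.fit_wavenumbers(px, py, RATE, PITCH, (0.0, 2.0))
        assert ev.accepted
        assert ev.p_x < 0.01 and ev.p_y < 0.01
        expected_alpha = np.cos(np.radians(45)) / 100.0
        assert ev.alpha_x == pytest.approx(expected_alpha, rel=0.05)
        assert ev.alpha_y == pytest.approx(expected_alpha, rel=0.05)
        assert ev.speed_mm_s == pytest.approx(100.0, rel=0.05)

    def test_axis_aligned_wave_literal_vs_any_axis(self):
        movie, _ = make_wave_movie(100.0, 0.0, 15.0)
        px, _ = waves.spacetime_project(movie.gevi, "x", PITCH)
        py, _ = waves.spacetime_project(movie.gevi, "y", PITCH)
        literal = waves.fit_wavenumbers(px, py, RATE, PITCH, (0.0, 2.0))
        assert not literal.accepted
        relaxed = waves.fit_wavenumbers(px, py, RATE, PITCH, (0.0, 2.0),
                                        any_axis=True)
        assert relaxed.accepted
        assert relaxed.alpha_y == 0.0
        assert abs((relaxed.direction_deg + 180) % 360 - 180) < 2.0

    def test_standing_oscillation_rejected(self):
        t = np.arange(600) / RATE
        v = np.cos(2 * np.pi * 10 * t)[:, None, None] * np.ones((1, 16, 16))
        px, _ = waves.spacetime_project(v, "x", PITCH)
        py, _ = waves.spacetime_project(v, "y", PITCH)
        ev = waves.fit_wavenumbers(px, py, RATE, PITCH, (0.0, 2.0))
        assert not ev.accepted
        assert ev.reject_reason == "synchronous"


class TestEstimatorConsistency:
    @pytest.mark.parametrize("direction", [0.0, 45.0, 90.0, 135.0])
    def test_estimators_agree_on_noise_free_waves(self, direction):
        movie, _ = make_wave_movie(100.0, direction, 15.0)
        dm = waves.seed_delay_map(movie.gevi, RATE, PITCH, (32, 32),
                                  max_lag_s=0.03)
        plane = waves.fit_plane_velocity(dm, xmin=0.7)
        px, _ = waves.spacetime_project(movie.gevi, "x", PITCH)
        py, _ = waves.spacetime_project(movie.gevi, "y", PITCH)
        wn = waves.fit_wavenumbers(px, py, RATE, PITCH, (0.0, 2.0),
                                   any_axis=True)
        assert plane.speed_mm_s == pytest.approx(wn.speed_mm_s, rel=0.10)
        diff = (plane.direction_deg - wn.direction_deg + 180) % 360 - 180
        assert abs(diff) < 10.0
        diff_true = (plane.direction_deg - direction + 180) % 360 - 180
        assert abs(diff_true) < 5.0

    def test_rotation_equivariance(self):
        movie, _ = make_wave_movie(100.0, 30.0, 15.0)
        v = movie.gevi
        # rotating frames by 90 deg CCW maps direction th -> th + 90
        v_rot = np.rot90(v, k=-1, axes=(1, 2)).copy()
        results = []
        for arr in (v, v_rot):
            ny, nx = arr.shape[1:]
            dm = waves.seed_delay_map(arr, RATE, PITCH, (ny // 2, nx // 2),
                                      max_lag_s=0.03)
            results.append(waves.fit_plane_velocity(dm, xmin=0.7))
        base, rot = results
        assert rot.speed_mm_s == pytest.approx(base.speed_mm_s, rel=0.02)
        diff = (rot.direction_deg - base.direction_deg - 90 + 180) % 360 - 180
        assert abs(diff) < 2.0


class TestFlowMap:
    def test_uniform_wave_gives_parallel_vectors(self):
        movie, _ = make_wave_movie(100.0, 45.0, 15.0, shape=(600, 32, 32))
        dm = waves.seed_delay_map(movie.gevi, RATE, PITCH, (16, 16),
                                  max_lag_s=0.03)
        fm = waves.flow_map(dm, grid_spacing=4)
        ux = fm[..., 0].ravel()
        uy = fm[..., 1].ravel()
        angles = np.degrees(np.arctan2(uy, ux))
        angles = angles[np.isfinite(angles)]
        # circular spread
        r = np.abs(np.mean(np.exp(1j * np.radians(angles))))
        circ_sd = np.degrees(np.sqrt(-2 * np.log(r)))
        assert circ_sd < 2.0
        mean_dir = np.degrees(np.angle(np.mean(np.exp(1j * np.radians(angles)))))
        assert abs((mean_dir - 45 + 180) % 360 - 180) < 3.0

    def test_radial_delay_field_points_outward(self):
        yy, xx = np.mgrid[-8:8, -8:8]
        delay = np.sqrt(xx ** 2 + yy ** 2) * 1e-3
        dmap = waves.DelayMap(corr=np.ones((16, 16)), delay_s=delay,
                              seed_yx=(8, 8), pixel_pitch_mm=0.1)
        fm = waves.flow_map(dmap)
        # at (8, 12) (i.e. +x side) the flow points along +x
        assert fm[8, 12, 0] > 0.9

    def test_empty_field_returns_nans(self):
        dmap = waves.DelayMap(corr=np.zeros((4, 4)),
                              delay_s=np.zeros((4, 4)), seed_yx=(0, 0),
                              pixel_pitch_mm=0.1,
                              valid_mask=np.zeros((4, 4), bool))
        fm = waves.flow_map(dmap)
        assert np.isnan(fm).all()
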