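"""Forward-model correctness of the microscopy simulator."""

import numpy as np
import pytest
from shapely.geometry import LinearRing, Point, Polygon

from soma_spt import (
    BlinkModel,
    MotionPhase,
    PSFModel,
    make_cell_geometry,
    render_movie,
    simulate_cell_zstack,
    simulate_trajectory,
)
from soma_spt._gauss import gaussian_spot
from soma_spt.synthetic_data import simulate_blink_states


class TestSimulateTrajectory:
    def test_stationary_phase_holds_position(self):
        tr = simulate_trajectory(
            [MotionPhase(kind="stationary", duration=10 / 9)], dt=1 / 9,
            origin=(1.0, 2.0, 0.5), seed=0,
        )
        assert np.allclose(tr.positions, [1.0, 2.0, 0.5])
        assert list(tr.phase_labels) == ["stationary"] * len(tr)

    def test_directed_straight_line_net_displacement(self):
        tr = simulate_trajectory(
            [MotionPhase(kind="directed", duration=10.0, v=1.0)], dt=1 / 9,
            origin=(0, 0, 0), seed=0,
        )
        net = np.linalg.norm(tr.positions[-1, :2] - tr.positions[0, :2])
        assert net == pytest.approx(10.0, abs=1e-9)

    def test_brownian_step_variance_matches_2_D_dt(self):
        D, dt = 0.29, 1 / 9
        tr = simulate_trajectory(
            [MotionPhase(kind="brownian", duration=10_000 * dt, D=D)], dt=dt,
            origin=(0, 0, 0), seed=1,
        )
        steps = np.diff(tr.positions[:, :2], axis=0)
        # sample variance of Gaussian: relative SE ~ sqrt(2/n)
        expected = 2 * D * dt
        assert np.allclose(steps.var(axis=0), expected, rtol=5 * np.sqrt(2 / len(steps)))

    def test_confined_phase_stays_in_corral(self):
        L = 0.5
        tr = simulate_trajectory(
            [MotionPhase(kind="confined", duration=50.0, D=0.29, L=L)], dt=1 / 9,
            origin=(3.0, 3.0, 0), seed=2,
        )
        assert np.all(np.abs(tr.positions[:, :2] - [3.0, 3.0]) <= L / 2 + 1e-12)

    def test_brownian_truth_msd_matches_4_D_dt(self):
        # brute-force MSD over all frame pairs of the raw truth positions
        D, dt = 0.29, 1 / 9
        tr = simulate_trajectory(
            [MotionPhase(kind="brownian", duration=4000 * dt, D=D)], dt=dt,
            origin=(0, 0, 0), seed=3,
        )
        xy = tr.positions[:, :2]
        n = len(xy)
        for k in (1, 2, 5):
            d2 = [((xy[i + k] - xy[i]) ** 2).sum() for i in range(n - k)]
            assert np.mean(d2) == pytest.approx(4 * D * k * dt, rel=0.15)

    def test_errors(self):
        with pytest.raises(ValueError):
            simulate_trajectory([MotionPhase(kind="stationary", duration=1)], dt=0)
        with pytest.raises(ValueError):
            MotionPhase(kind="levitating", duration=1)
        with pytest.raises(ValueError):
            MotionPhase(kind="confined", duration=1, L=0)


class TestRenderMovie:
    def test_empty_scene_is_exactly_offset(self, camera, never_blink):
        psf = PSFModel(sigma=1.2, photons_on=1.0, background=0.0)
        movie, truth = render_movie([], camera, psf, never_blink, 3, (16, 16), seed=0)
        assert np.all(movie == camera.offset)
        assert truth.empty

    def test_mean_frame_matches_analytic_expectation(self, camera, psf, never_blink):
        # long-run average of the peak pixel vs the forward-model mean
        tr = simulate_trajectory(
            [MotionPhase(kind="stationary", duration=10_000)], dt=1.0,
            origin=(4.5 * camera.pixel_size, 4.5 * camera.pixel_size, 0), seed=0,
        )
        movie, _ = render_movie([tr], camera, psf, never_blink, 10_000, (9, 9), seed=4)
        mass = gaussian_spot((9, 9), 4.5, 4.5, psf.sigma)[4, 4]
        lam_peak = psf.background + psf.photons_on * mass
        expect = camera.offset + camera.gain * lam_peak
        se = camera.gain * np.sqrt(lam_peak / movie.shape[0])
        assert abs(movie[:, 4, 4].mean() - expect) < 3 * se

    def test_photon_conservation_noise_free(self, camera, psf, never_blink):
        tr = simulate_trajectory(
            [MotionPhase(kind="stationary", duration=2)], dt=1.0,
            origin=(16 * 0.127, 16 * 0.127, 0), seed=0,
        )
        movie, _ = render_movie(
            [tr], camera, psf, never_blink, 1, (32, 32), seed=0, poisson_noise=False
        )
        photons = (movie[0] - camera.offset) / camera.gain
        assert photons.sum() == pytest.approx(
            psf.background * 32 * 32 + psf.photons_on, rel=1e-6
        )

    def test_blink_on_fraction_matches_stationary_law(self, camera, never_blink):
        blink = BlinkModel(p_off=0.1, p_on=0.5)
        states = simulate_blink_states(blink, 10_000, np.random.default_rng(1))
        assert states.mean() == pytest.approx(5 / 6, abs=0.02)

    def test_off_emitter_contributes_nothing(self, camera, psf):
        blink_off = BlinkModel(p_off=1.0, p_on=0.0, initial_state="off")
        tr = simulate_trajectory(
            [MotionPhase(kind="stationary", duration=3)], dt=1.0,
            origin=(1.0, 1.0, 0), seed=0,
        )
        psf0 = PSFModel(sigma=psf.sigma, photons_on=psf.photons_on, background=0.0)
        movie, truth = render_movie(
            [tr], camera, psf0, blink_off, 3, (16, 16), seed=0, poisson_noise=False
        )
        assert np.all(movie == camera.offset)
        assert not truth.on.any()

    def test_reproducibility_bit_identical(self, camera, psf, never_blink):
        tr = simulate_trajectory(
            [MotionPhase(kind="brownian", duration=10, D=0.1)], dt=1.0,
            origin=(1.5, 1.5, 0), seed=7,
        )
        m1, t1 = render_movie([tr], camera, psf, never_blink, 5, (24, 24), seed=42)
        m2, t2 = render_movie([tr], camera, psf, never_blink, 5, (24, 24), seed=42)
        assert np.array_equal(m1, m2)
        assert t1.equals(t2)

    def test_out_of_field_raises(self, camera, psf, never_blink):
        tr = simulate_trajectory(
            [MotionPhase(kind="stationary", duration=2)], dt=1.0,
            origin=(100.0, 1.0, 0), seed=0,
        )
        with pytest.raises(ValueError, match="field of view"):
            render_movie([tr], camera, psf, never_blink, 2, (16, 16), seed=0)


class TestCellZStack:
    def test_no_qds_is_pure_background(self, camera, psf):
        geom = make_cell_geometry(n_planes=5, mean_radius_um=4.0, seed=0)
        qd, mem, truth = simulate_cell_zstack(
            geom, 0, 0.5, camera=camera, psf=psf, seed=0, image_shape=(96, 96)
        )
        assert truth.empty
        counts = (qd - camera.offset) / camera.gain
        assert counts.mean() == pytest.approx(psf.background, rel=0.05)
        assert counts.max() < psf.background + 8 * np.sqrt(psf.background)

    def test_all_internal_placement_respects_margin(self, camera, psf):
        geom = make_cell_geometry(n_planes=9, mean_radius_um=5.0, seed=1)
        _, _, truth = simulate_cell_zstack(
            geom, 20, 1.0, camera=camera, psf=psf, seed=1, image_shape=(256, 256)
        )
        assert (truth.label == "internal").all()
        for _, row in truth.iterrows():
            poly = Polygon(geom.contours[int(row.plane)])
            pt = Point(row.x_um, row.y_um)
            assert poly.contains(pt)
            assert pt.distance(LinearRing(geom.contours[int(row.plane)])) >= 0.5 - 1e-9

    def test_internal_membrane_split_rounds(self, camera, psf):
        geom = make_cell_geometry(n_planes=11, mean_radius_um=6.0, seed=2)
        _, _, truth = simulate_cell_zstack(
            geom, 50, 0.9, camera=camera, psf=psf, seed=2, image_shape=(256, 256)
        )
        assert (truth.label == "internal").sum() == 45
        assert (truth.label == "membrane").sum() == 5

    def test_membrane_points_near_contour(self, camera, psf):
        geom = make_cell_geometry(n_planes=9, mean_radius_um=5.0, seed=3)
        _, _, truth = simulate_cell_zstack(
            geom, 10, 0.0, camera=camera, psf=psf, seed=3, image_shape=(256, 256)
        )
        for _, row in truth.iterrows():
            ring = LinearRing(geom.contours[int(row.plane)])
            assert Point(row.x_um, row.y_um).distance(ring) <= 0.1 + 1e-9

    def test_each_qd_spans_at_least_three_planes(self, camera, psf):
        geom = make_cell_geometry(n_planes=9, mean_radius_um=5.0, seed=4)
        qd, _, truth = simulate_cell_zstack(
            geom, 5, 1.0, camera=camera, psf=psf, seed=4, image_shape=(256, 256)
        )
        from soma_spt.synthetic_data import _axial_weight

        for _, row in truth.iterrows():
            n_support = sum(
                _axial_weight(row.z_um - geom.plane_z(j), geom.z_step) > 0.1
                for j in range(geom.n_planes)
            )
            assert n_support >= 3
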