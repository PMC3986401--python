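"""MSD analysis, smooth paths, speeds, phase segmentation and blinking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soma_spt import (
    BlinkModel,
    MotionPhase,
    MSDCurve,
    classify_single_qd,
    compute_msd,
    estimate_speeds,
    fit_msd,
    fit_smooth_path,
    intensity_trace,
    path_position,
    segment_phases,
    simulate_trajectory,
)
from soma_spt.dynamics import IntensityTrace
from soma_spt.synthetic_data import simulate_blink_states
from helpers import make_trajectory


def _brute_force_msd(frames, xy):
    """O(N²) double-loop MSD oracle over all frame pairs."""
    out = {}
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            k = frames[j] - frames[i]
            out.setdefault(k, []).append(((xy[j] - xy[i]) ** 2).sum())
    return {k: np.mean(v) for k, v in out.items()}


class TestComputeMSD:
    def test_stationary_msd_is_zero(self):
        tj = make_trajectory(np.arange(20) * 0.1, np.ones((20, 2)))
        assert np.all(compute_msd(tj).msd == 0.0)

    def test_ballistic_closed_form(self):
        v, dt = 0.7, 0.5
        t = np.arange(40) * dt
        tj = make_trajectory(t, np.column_stack([v * t, np.zeros(40)]))
        m = compute_msd(tj)
        assert np.allclose(m.msd, (v * m.lags_s) ** 2)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 24
        xy = np.cumsum(rng.normal(0, 0.2, (n, 2)), axis=0)
        tj = make_trajectory(np.arange(n) * 0.1, xy)
        m = compute_msd(tj, max_lag_frames=n - 1)
        oracle = _brute_force_msd(np.arange(n), xy)
        for lag, msd, npair in zip(m.lags_s, m.msd, m.n_pairs):
            k = int(round(lag / 0.1))
            assert msd == pytest.approx(oracle[k], rel=1e-9)
            assert npair == n - k

    def test_gap_frames_excluded_from_pairs(self):
        n = 20
        xy = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        gap = np.zeros(n, bool)
        gap[7] = True
        tj = make_trajectory(np.arange(n) * 1.0, xy, gap=gap)
        m = compute_msd(tj, max_lag_frames=3)
        # lag-1 pairs lose the two pairs that touch the bridged frame
        assert m.n_pairs[0] == (n - 1) - 2

    def test_short_trajectory_rejected(self):
        tj = make_trajectory(np.arange(5) * 0.1, np.zeros((5, 2)))
        with pytest.raises(ValueError):
            compute_msd(tj)


class TestFitMSD:
    def test_noiseless_free_model_inverted(self):
        lags = np.arange(1, 20) * 0.1
        m = MSDCurve(lags_s=lags, msd=4 * 0.5 * lags, n_pairs=np.full(len(lags), 100), dt=0.1)
        fit = fit_msd(m)
        assert fit.model == "free"
        assert fit.D == pytest.approx(0.5, abs=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)

    def test_brownian_diffusion_coefficient_recovered(self):
        # membrane-phase diffusion: D = 0.29 µm²/s at 9 frames/s with
        # 30 nm localization noise, 20 replicate trajectories
        rng = np.random.default_rng(14)
        D_true, dt = 0.29, 1 / 9
        Ds = []
        for _ in range(20):
            tr = simulate_trajectory(
                [MotionPhase(kind="brownian", duration=1000 * dt, D=D_true)], dt,
                (0, 0, 0), rng,
            )
            xy = tr.positions[:, :2] + rng.normal(0, 0.03, (len(tr), 2))
            fit = fit_msd(compute_msd(make_trajectory(tr.times, xy)))
            Ds.append(fit.D)
        assert np.mean(Ds) == pytest.approx(D_true, rel=0.10)

    def test_corral_model_selected_and_sized(self):
        rng = np.random.default_rng(15)
        L_true = 0.5
        Ls = []
        for _ in range(10):
            tr = simulate_trajectory(
                [MotionPhase(kind="confined", duration=111, D=0.29, L=L_true)], 1 / 9,
                (0, 0, 0), rng,
            )
            xy = tr.positions[:, :2] + rng.normal(0, 0.01, (len(tr), 2))
            fit = fit_msd(compute_msd(make_trajectory(tr.times, xy)))
            assert fit.model == "corralled"
            Ls.append(fit.L)
        assert np.mean(Ls) == pytest.approx(L_true, rel=0.20)

    def test_ballistic_input_flagged_as_poor_fit(self):
        t = np.arange(40) * 0.5
        tj = make_trajectory(t, np.column_stack([0.7 * t, np.zeros(40)]))
        fit = fit_msd(compute_msd(tj))
        assert not fit.model_ok

    def test_free_fit_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(16)
        tr = simulate_trajectory(
            [MotionPhase(kind="brownian", duration=100, D=0.29)], 1 / 9, (0, 0, 0), rng
        )
        xy = tr.positions[:, :2]
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy2 = xy @ R.T + [5.0, -2.0]
        f1 = fit_msd(compute_msd(make_trajectory(tr.times, xy)))
        f2 = fit_msd(compute_msd(make_trajectory(tr.times, xy2)))
        assert f1.D == pytest.approx(f2.D, rel=1e-9)


class TestSmoothPathAndSpeeds:
    def test_collinear_arc_length_equals_net(self):
        t = np.arange(50) * 0.2
        tj = make_trajectory(t, np.column_stack([0.3 * t, 0.4 * t]))
        p = fit_smooth_path(tj, method="poly2")
        assert p.arc_length == pytest.approx(0.5 * t[-1], abs=1e-6)

    def test_semicircle_arc_length_analytic(self):
        t = np.linspace(0, 10, 200)
        ang = np.pi * t / 10
        tj = make_trajectory(t, np.column_stack([3 * np.cos(ang), 3 * np.sin(ang)]))
        p = fit_smooth_path(tj, method="spline")
        assert p.arc_length == pytest.approx(3 * np.pi, rel=0.01)

    def test_path_position_straight_line_exact(self):
        t = np.arange(30) * 0.5
        tj = make_trajectory(t, np.column_stack([0.8 * t, np.zeros(30)]))
        path = fit_smooth_path(tj, method="poly2")
        _, s = path_position(tj, path)
        assert np.allclose(s, 0.8 * t, atol=0.02)

    def test_noisy_semicircle_positions_within_noise(self):
        rng = np.random.default_rng(17)
        sigma = 0.02
        t = np.linspace(0, 10, 300)
        ang = np.pi * t / 10
        truth_s = 3.0 * ang
        xy = np.column_stack([3 * np.cos(ang), 3 * np.sin(ang)]) + rng.normal(
            0, sigma, (300, 2)
        )
        tj = make_trajectory(t, xy)
        path = fit_smooth_path(tj, method="spline")
        _, s = path_position(tj, path)
        assert np.sqrt(np.mean((s - truth_s) ** 2)) <= 2 * sigma + 0.05

    def test_speed_exact_slope_and_sign(self):
        t = np.arange(100) * 0.1
        _, v = estimate_speeds(t, 0.8 * t, window_s=2.0)
        assert np.allclose(v, 0.8, atol=1e-9)
        _, v = estimate_speeds(t, -0.5 * t, window_s=2.0)
        assert np.all(v < 0)

    def test_speed_pipeline_noiseless_roundtrip(self):
        # estimate_speeds ∘ path_position on constant-speed directed
        # motion returns the input speed within 1e-3
        t = np.arange(200) * 0.1
        tj = make_trajectory(t, np.column_stack([0.8 * t, np.zeros(200)]))
        path = fit_smooth_path(tj, method="poly2")
        ts, s = path_position(tj, path)
        _, v = estimate_speeds(ts, s, window_s=2.0)
        assert np.mean(v) == pytest.approx(0.8, abs=1e-3)

    def test_underdetermined_fit_raises(self):
        tj = make_trajectory([0, 1, 2], np.zeros((3, 2)))
        with pytest.raises(ValueError):
            fit_smooth_path(tj, method="poly2")

    def test_window_longer_than_record_raises(self):
        with pytest.raises(ValueError):
            estimate_speeds(np.arange(5) * 0.1, np.arange(5) * 0.1, window_s=2.0)


class TestSegmentPhases:
    def test_all_stationary_single_immobile_segment(self):
        tr = simulate_trajectory(
            [MotionPhase(kind="stationary", duration=10)], 1 / 9, (0, 0, 0), seed=1
        )
        segs = segment_phases(make_trajectory(tr.times, tr.positions[:, :2]))
        assert len(segs) == 1
        assert segs[0].kind == "immobile"
        assert segs[0].start_s == 0.0 and segs[0].end_s == pytest.approx(10.0, abs=0.2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_directed_confined_directed_recovered(self, seed):
        phases = [
            MotionPhase(kind="directed", duration=10, v=1.0),
            MotionPhase(kind="confined", duration=60, D=0.05, L=0.5),
            MotionPhase(kind="directed", duration=10, v=1.0, path=np.array([[0, 0], [20, 20]])),
        ]
        tr = simulate_trajectory(phases, 1 / 9, (0, 0, 0), seed=seed)
        xy = tr.positions[:, :2] + np.random.default_rng(100 + seed).normal(
            0, 0.02, (len(tr), 2)
        )
        segs = segment_phases(make_trajectory(tr.times, xy), loc_sigma_um=0.02)
        assert [s.kind for s in segs] == ["directed", "confined", "directed"]
        assert segs[0].end_s == pytest.approx(10.0, abs=2.0)
        assert segs[1].end_s == pytest.approx(70.0, abs=2.0)

    def test_pure_brownian_majority_diffusive(self):
        tr = simulate_trajectory(
            [MotionPhase(kind="brownian", duration=60, D=0.29)], 1 / 9, (0, 0, 0), seed=7
        )
        xy = tr.positions[:, :2] + np.random.default_rng(8).normal(0, 0.03, (len(tr), 2))
        segs = segment_phases(make_trajectory(tr.times, xy))
        total = sum(s.end_s - s.start_s for s in segs)
        diffusive = sum(s.end_s - s.start_s for s in segs if s.kind == "diffusive")
        assert diffusive / total >= 0.7


class TestIntensityTrace:
    def test_zero_movie_all_zero(self):
        movie = np.zeros((10, 32, 32))
        tj = make_trajectory(np.arange(10) * 0.1, np.full((10, 2), 16 * 0.127))
        trace = intensity_trace(movie, tj)
        assert np.all(trace.values == 0.0)

    def test_always_on_emitter_analytic_mean(self, camera, psf, never_blink):
        from soma_spt import calibrate, render_movie
        from soma_spt._gauss import gaussian_spot

        x_px = y_px = 16.0  # emitter on a pixel corner for a symmetric window
        tr = simulate_trajectory(
            [MotionPhase(kind="stationary", duration=400)], 1.0,
            (x_px * camera.pixel_size, y_px * camera.pixel_size, 0), seed=0,
        )
        movie, _ = render_movie([tr], camera, psf, never_blink, 400, (32, 32), seed=18)
        counts = np.stack([calibrate(f, camera).counts for f in movie])
        tj = make_trajectory(tr.times[:400], tr.positions[:400, :2])
        trace = intensity_trace(counts, tj, camera.pixel_size)
        # the 6x6 window for a particle at pixel index 16 spans pixels 14..19
        spot = psf.photons_on * gaussian_spot((32, 32), x_px, y_px, psf.sigma)
        mass = spot[14:20, 14:20].sum()
        expect = mass + 36 * psf.background
        se = np.sqrt(expect / 400)
        assert abs(np.nanmean(trace.values) - expect) < 4 * se

    def test_blink_dip_to_background(self, camera, psf):
        from soma_spt import calibrate
        from soma_spt._gauss import gaussian_spot

        rng = np.random.default_rng(19)
        n = 30
        movie = np.empty((n, 32, 32))
        for f in range(n):
            lam = psf.background + (
                0 if 10 <= f < 20 else psf.photons_on
            ) * gaussian_spot((32, 32), 16.0, 16.0, psf.sigma)
            movie[f] = camera.gain * rng.poisson(lam) + camera.offset
        counts = np.stack([calibrate(f, camera).counts for f in movie])
        tj = make_trajectory(
            np.arange(n) * 0.1, np.full((n, 2), 16 * camera.pixel_size)
        )
        trace = intensity_trace(counts, tj, camera.pixel_size)
        off_mean = trace.values[10:20].mean()
        assert off_mean == pytest.approx(36 * psf.background, abs=5 * np.sqrt(360 / 10))
        assert trace.values[:10].mean() > off_mean + 300


class TestClassifySingleQD:
    def _trace(self, n, n_emitters, rng, p_off=0.3, p_on=0.3):
        vals = np.zeros(n)
        for _ in range(n_emitters):
            st_ = simulate_blink_states(BlinkModel(p_off=p_off, p_on=p_on), n, rng)
            vals += np.where(st_, 760.0, 0.0)
        return IntensityTrace(
            frames=np.arange(n), values=rng.poisson(vals + 360.0).astype(float)
        )

    def test_single_blinking_qd_recognized(self):
        rng = np.random.default_rng(20)
        verdicts = [classify_single_qd(self._trace(200, 1, rng))[0] for _ in range(50)]
        assert verdicts.count("single") / 50 >= 0.9

    def test_two_superimposed_qds_called_multiple(self):
        rng = np.random.default_rng(21)
        verdicts = [classify_single_qd(self._trace(200, 2, rng))[0] for _ in range(100)]
        assert verdicts.count("multiple") / 100 >= 0.8

    def test_constant_trace_indeterminate(self):
        rng = np.random.default_rng(22)
        trace = IntensityTrace(
            frames=np.arange(100), values=rng.poisson(1000, 100).astype(float)
        )
        assert classify_single_qd(trace)[0] == "indeterminate"

    def test_short_trace_rejected(self):
        trace = IntensityTrace(frames=np.arange(10), values=np.ones(10))
        with pytest.raises(ValueError):
            classify_single_qd(trace)
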