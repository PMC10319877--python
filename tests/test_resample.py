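"""1 Hz interpolation contract and validation statistics."""

import numpy as np
import pandas as pd
import pytest

from pedtraj.kinematics import attach_steps, compute_steps, summarize
from pedtraj.records import Trajectory
from pedtraj.resample import (
    compare_pre_post_interpolation,
    interpolate_1hz,
    log_velocity,
    msd,
    velocity_autocorrelation,
    _autocorr_1traj,
)
from pedtraj.simulate import M_PER_DEG_LAT

from conftest import make_track, straight_track, track_from_speeds


class TestInterpolation:
    def test_linear_insertion(self):
        traj = make_track(
            [[0.0, 0.0], [0.00004, 0.0]], seconds=np.array([0, 4])
        )
        out = interpolate_1hz(traj)
        assert len(out) == 5
        assert np.allclose(
            out.df["latitude"], [0.0, 0.00001, 0.00002, 0.00003, 0.00004]
        )

    def test_uniform_track_is_identity(self):
        traj = straight_track(n=50)
        out = interpolate_1hz(traj)
        assert len(out) == 50
        assert np.allclose(out.df["latitude"], traj.df["latitude"])
        assert np.allclose(out.df["longitude"], traj.df["longitude"])
        assert (out.df["time"].values == traj.df["time"].values).all()

    def test_contract_dt_one_and_d_equals_v(self, rng):
        speeds = rng.uniform(0.5, 2.5, 300)
        traj = track_from_speeds(speeds)
        # knock out ~17% of interior records to create gaps
        drop = rng.choice(np.arange(1, 300), size=50, replace=False)
        traj = traj.replace_df(traj.df.drop(traj.df.index[drop]))
        out = interpolate_1hz(traj)
        assert out.steps is not None
        assert np.all(out.steps.dt == 1.0)
        assert np.array_equal(out.steps.dist, out.steps.vel)

    def test_endpoints_duration_distance_invariant(self, rng):
        speeds = rng.uniform(0.5, 2.5, 400)
        traj = track_from_speeds(speeds)  # collinear (northbound)
        drop = rng.choice(np.arange(1, 400), size=70, replace=False)
        traj = traj.replace_df(traj.df.drop(traj.df.index[drop]))
        pre = summarize(traj)
        out = interpolate_1hz(traj)
        post = summarize(out)
        assert out.df["time"].iloc[0] == traj.df["time"].iloc[0]
        assert out.df["time"].iloc[-1] == traj.df["time"].iloc[-1]
        assert post.T == pre.T
        # collinear segments: inserted fixes add no path length
        assert post.D == pytest.approx(pre.D, rel=1e-9)

    def test_non_integer_timestamp_rejected(self):
        traj = straight_track(n=10)
        df = traj.df.copy()
        df["time"] = df["time"] + pd.Timedelta(milliseconds=500)
        df.loc[0, "time"] = traj.df["time"].iloc[0]
        with pytest.raises(ValueError, match="non-integer"):
            interpolate_1hz(Trajectory(df=df))

    def test_gap_ledger_predicts_inflation(self, default_cohort):
        trajs, ledger = default_cohort
        peds = [
            t for t in trajs
            if ledger.trajectories[t.source_filename].cls == "pedestrian"
        ][:15]
        for t in peds:
            extra = len(interpolate_1hz(t)) - len(t)
            assert extra == ledger.trajectories[t.source_filename].gap_extra_seconds


class TestLogVelocity:
    def test_constant_velocity_gives_zero(self):
        steps = compute_steps(straight_track(v=1.5, n=100))
        series = log_velocity(steps, v_m=1.5)
        assert np.allclose(series.u, 0.0, atol=1e-9)

    def test_e_fold_gives_one(self):
        v_m = 1.2
        speeds = np.full(50, v_m)
        speeds[10] = np.e * v_m
        steps = compute_steps(track_from_speeds(speeds))
        series = log_velocity(steps, v_m=v_m)
        assert series.u[10] == pytest.approx(1.0, abs=1e-6)

    def test_zero_velocity_steps_excluded(self):
        speeds = np.array([1.5, 0.0, 1.5, 1.5])
        series = log_velocity(compute_steps(track_from_speeds(speeds)))
        assert series.n_excluded == 1
        assert np.isnan(series.u[1])

    def test_lognormal_mean_matches_closed_form(self, rng):
        # v lognormal(mu, s): E[u] = E[ln v] - ln v_m = mu - ln(mean(v))
        mu, s, n = 0.4, 0.3, 20000
        v = rng.lognormal(mu, s, n)
        series = log_velocity(compute_steps(track_from_speeds(v)))
        expected = mu - np.log(v.mean())
        se = s / np.sqrt(n)
        assert abs(np.nanmean(series.u) - expected) < 3 * se

    def test_all_zero_raises(self):
        steps = compute_steps(track_from_speeds(np.zeros(10)))
        with pytest.raises(ValueError):
            log_velocity(steps)


class TestMSD:
    def test_ballistic_closed_form(self):
        traj = straight_track(v=1.5, n=600)
        curve = msd([traj], max_lag=100, n_boot=50)
        tau = curve.lags[1:]
        expected = (1.5 * tau) ** 2
        assert np.allclose(curve.msd[1:], expected, rtol=1e-3)
        assert curve.msd[0] == 0.0

    def test_stationary_track_zero(self):
        traj = make_track(np.tile([41.4, 2.0], (50, 1)), seconds=np.arange(50))
        curve = msd([traj], max_lag=10, n_boot=20)
        assert np.allclose(curve.msd, 0.0, atol=1e-12)

    def test_lattice_random_walk_diffusive(self, rng):
        # 2-D random walk, 1 m steps: MSD(tau) ~ tau * (1 m²)
        trajs = []
        for _ in range(40):
            steps = rng.choice([(1, 0), (-1, 0), (0, 1), (0, -1)], size=400)
            xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            latlon = np.column_stack(
                [41.4 + xy[:, 1] / M_PER_DEG_LAT,
                 2.0 + xy[:, 0] / (M_PER_DEG_LAT * np.cos(np.radians(41.4)))]
            )
            trajs.append(make_track(latlon))
        curve = msd(trajs, max_lag=20, n_boot=300, rng=rng)
        for tau in (5, 10, 20):
            assert curve.ci_low[tau] <= tau <= curve.ci_high[tau]

    def test_ci_brackets_estimate(self, default_cohort):
        trajs, ledger = default_cohort
        peds = [
            attach_steps(t) for t in trajs
            if ledger.trajectories[t.source_filename].cls == "pedestrian"
        ][:10]
        curve = msd(peds, max_lag=30, n_boot=100)
        assert np.all(curve.ci_low <= curve.msd + 1e-9)
        assert np.all(curve.msd <= curve.ci_high + 1e-9)


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        trajs = [track_from_speeds(rng.uniform(0.5, 2.5, 200)) for _ in range(5)]
        curve = velocity_autocorrelation(trajs, max_lag=5, n_boot=50, rng=rng)
        assert curve.c[0] == 1.0

    def test_white_noise_decorrelated(self):
        rng = np.random.default_rng(3)
        trajs = [
            track_from_speeds(1.5 * np.exp(rng.normal(0, 0.3, 600)))
            for _ in range(30)
        ]
        curve = velocity_autocorrelation(
            trajs, max_lag=3, n_boot=400, rng=np.random.default_rng(4)
        )
        for tau in (1, 2, 3):
            assert curve.ci_low[tau] <= 0.0 <= curve.ci_high[tau]

    def test_ar1_recovers_coefficient(self):
        rng = np.random.default_rng(5)
        rho, n, n_traj = 0.6, 2000, 40
        trajs = []
        for _ in range(n_traj):
            e = rng.normal(0, 0.3, n)
            u = np.empty(n)
            u[0] = e[0]
            for i in range(1, n):
                u[i] = rho * u[i - 1] + e[i]
            trajs.append(track_from_speeds(1.5 * np.exp(u)))
        curve = velocity_autocorrelation(trajs, max_lag=1, n_boot=100, rng=rng)
        per = np.array(
            [
                _autocorr_1traj(log_velocity(compute_steps(t)).u, 1)[1]
                for t in trajs
            ]
        )
        se = per.std(ddof=1) / np.sqrt(n_traj)
        assert abs(curve.c[1] - rho) < 3 * se


class TestPrePostComparison:
    def test_T_and_D_preserved(self, rng):
        speeds = rng.uniform(0.8, 2.2, 300)
        pre = []
        for i in range(5):
            t = track_from_speeds(speeds, nickname=f"zaf_{i:04d}_walk")
            drop = rng.choice(np.arange(1, 300), size=40, replace=False)
            t = t.replace_df(t.df.drop(t.df.index[drop]))
            t.source_filename = f"2018-11-05_zaf_{i:04d}_walk.csv"
            pre.append(attach_steps(t))
        post = []
        for t in pre:
            it = interpolate_1hz(t)
            it.source_filename = t.source_filename
            post.append(it)
        rep = compare_pre_post_interpolation(pre, post)
        tab = rep["per_trajectory"]
        assert np.allclose(tab["T_pre"], tab["T_post"])
        assert np.allclose(tab["D_pre"], tab["D_post"], rtol=1e-9)
        assert np.allclose(tab["veff_pre"], tab["veff_post"], rtol=1e-9)
        # inserted gap-filling steps shift the mean velocity down slightly
        assert rep["v_mean_post"] <= rep["v_mean_pre"] + 1e-9
        assert rep["n_records_post"] > rep["n_records_pre"]

    def test_cohort_mismatch_raises(self):
        a = attach_steps(straight_track(nickname="zaf_0001_walk"))
        b = attach_steps(straight_track(nickname="zaf_0002_walk"))
        with pytest.raises(ValueError):
            compare_pre_post_interpolation([a], [b])
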