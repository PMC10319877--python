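"""Cleaning stages: non-pedestrian filter, OD validation, outlier removal."""

import numpy as np
import pytest

from pedtraj.cleaning import (
    CleaningPolicy,
    NonPedestrianFilter,
    OriginDestinationValidator,
    OutlierRemover,
    remove_outliers,
    traj_key,
    validate_origin_destination,
)
from pedtraj.kinematics import compute_steps
from pedtraj.simulate import M_PER_DEG_LAT

from conftest import SCHOOL, commute_track, make_track, straight_track, track_from_speeds


def burst_track(n_burst=5, v_burst=90.0, v_walk=1.4, n_walk=300):
    """Leading GPS-activation spikes followed by a clean walk."""
    rng = np.random.default_rng(0)
    walk = v_walk * np.arange(n_walk)
    lat_walk = 41.40 + walk / M_PER_DEG_LAT
    # burst fixes alternate +/- v_burst meters around the walk start
    off = np.array([(v_burst / 2) * (-1) ** i for i in range(n_burst)])
    lat_burst = 41.40 + off / M_PER_DEG_LAT
    lat = np.concatenate([lat_burst, lat_walk])
    lon = np.full(len(lat), 2.0)
    return make_track(np.column_stack([lat, lon]))


class TestNonPedestrianFilter:
    def test_declared_vehicle_removed(self):
        traj = straight_track(v=1.4, nickname="sgv_0601_tren")
        step = NonPedestrianFilter().fit([traj])
        assert step.transform([traj]) == []
        assert step.report_.dispositions[traj_key(traj)] == "removed:mode=train"

    def test_walker_kept_regardless_of_speed_or_case(self):
        fast = straight_track(v=3.0, nickname="ZAF_0001_WALK_ALONE")
        slow = straight_track(v=1.4, nickname="zaf_0002_peu")
        kept = NonPedestrianFilter().fit([fast, slow]).transform([fast, slow])
        assert len(kept) == 2

    def test_unknown_mode_speed_threshold(self):
        fast = straight_track(v=6.0, nickname="zaf_0003")
        slow = straight_track(v=1.4, nickname="zaf_0004")
        step = NonPedestrianFilter(v_nonped=2.5).fit([fast, slow])
        kept = step.transform([fast, slow])
        assert [t.nickname for t in kept] == ["zaf_0004"]
        assert step.report_.dispositions[traj_key(fast)] == "removed:abnormal_velocity"

    def test_bookkeeping_identity(self):
        trajs = [
            straight_track(nickname="zaf_0001_walk"),
            straight_track(nickname="zaf_0002_bus"),
        ]
        step = NonPedestrianFilter().fit(trajs)
        step.transform(trajs)
        r = step.report_
        assert r.n_records_in == r.n_records_kept + r.n_records_removed
        assert set(r.dispositions) == {traj_key(t) for t in trajs}


class TestOriginDestination:
    def test_valid_commute(self):
        traj = commute_track(home_dist=600.0)  # ends at the school
        ok, reason = validate_origin_destination(traj, SCHOOL)
        assert ok, reason

    def test_scatter_blob_rejected(self):
        rng = np.random.default_rng(1)
        off = rng.uniform(-80, 80, (12, 2))
        latlon = np.column_stack(
            [SCHOOL[0] + off[:, 0] / M_PER_DEG_LAT, SCHOOL[1] + off[:, 1] / (M_PER_DEG_LAT * 0.75)]
        )
        traj = make_track(latlon)
        ok, reason = validate_origin_destination(traj, SCHOOL)
        assert not ok
        assert reason == "too_few_records"
        # same pattern with enough records trips the both-endpoints rule
        off = rng.uniform(-80, 80, (60, 2))
        latlon = np.column_stack(
            [SCHOOL[0] + off[:, 0] / M_PER_DEG_LAT, SCHOOL[1] + off[:, 1] / (M_PER_DEG_LAT * 0.75)]
        )
        ok, reason = validate_origin_destination(make_track(latlon), SCHOOL)
        assert not ok
        assert reason == "scatter_around_school"

    def test_no_school_endpoint_rejected(self):
        traj = straight_track(v=1.5, n=400, lat0=41.50, lon0=2.30)
        ok, reason = validate_origin_destination(traj, SCHOOL)
        assert not ok
        assert reason == "no_school_endpoint"

    def test_missing_school_coordinates_raises(self):
        traj = commute_track(nickname="zaf_0001_walk")
        step = OriginDestinationValidator(school_coords={"SGV": SCHOOL}).fit([traj])
        with pytest.raises(KeyError):
            step.transform([traj])

    def test_unmatched_school_routed_to_review(self):
        traj = commute_track(nickname="xyz_0001_walk")
        step = OriginDestinationValidator(school_coords={"ZAF": SCHOOL}).fit([traj])
        kept = step.transform([traj])
        assert kept == []
        assert len(step.review_) == 1
        assert step.report_.dispositions[traj_key(traj)] == "review:unmatched_school"


class TestOutlierRemoval:
    def test_leading_burst_removed_walk_kept(self):
        traj = burst_track(n_burst=5)
        cleaned, info = remove_outliers(traj)
        assert cleaned is not None
        assert sorted(info["removed"]) == [0, 1, 2, 3, 4]
        assert len(cleaned) == len(traj) - 5
        assert compute_steps(cleaned).vel.max() <= 10.0

    def test_clean_track_unchanged(self):
        traj = straight_track(v=1.4, n=200)
        cleaned, info = remove_outliers(traj)
        assert info["removed"] == []
        assert cleaned.df.equals(traj.df)

    def test_heavy_contamination_discards_whole_trajectory(self, rng):
        # 40% of records replaced by teleporting noise
        n = 200
        speeds = np.full(n - 1, 1.4)
        traj = track_from_speeds(speeds)
        df = traj.df.copy()
        noisy = rng.choice(n, size=int(0.4 * n), replace=False)
        df.loc[df.index[noisy], "latitude"] += rng.uniform(0.01, 0.02, len(noisy))
        traj = traj.replace_df(df)
        cleaned, info = remove_outliers(traj, CleaningPolicy(max_outlier_fraction=0.3))
        assert cleaned is None
        assert info["reason"] in ("too_many_outliers", "all_outliers")

    def test_spike_neighbours_survive(self):
        # one teleported record: it goes, its neighbours stay
        traj = track_from_speeds(np.full(99, 1.4))
        df = traj.df.copy()
        df.loc[50, "latitude"] += 100.0 / M_PER_DEG_LAT
        cleaned, info = remove_outliers(traj.replace_df(df))
        assert info["removed"] == [50]

    def test_haccuracy_cap(self):
        traj = straight_track(n=100)
        df = traj.df.copy()
        df.loc[10, "haccuracy"] = 500.0
        cleaned, info = remove_outliers(traj.replace_df(df))
        assert info["removed"] == [10]

    def test_terminal_dwell_collapsed_to_first_record(self):
        traj = commute_track(home_dist=450.0)
        n_walk = len(traj)
        df = traj.df.copy()
        # 120 s of near-stationary fixes appended at the school
        import pandas as pd

        tail = df.iloc[[-1]].copy()
        rows = []
        for i in range(1, 121):
            r = tail.copy()
            r["time"] = tail["time"].iloc[0] + pd.Timedelta(seconds=i)
            r["latitude"] += (i % 3) * 2.0 / M_PER_DEG_LAT  # <= 4 m jitter
            rows.append(r)
        df = pd.concat([df] + rows, ignore_index=True)
        traj2 = traj.replace_df(df)
        cleaned, info = remove_outliers(traj2)
        assert cleaned is not None
        # dwell collapsed: everything after its first record is gone
        assert len(cleaned) <= n_walk + 1
        assert not info["reason"]

    def test_order_stability(self, default_cohort):
        trajs, _ = default_cohort
        step = OutlierRemover().fit(trajs[:20])
        for after in step.transform(trajs[:20]):
            idx = list(after.df.index)
            assert idx == sorted(idx)  # deletions only, never permuted
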