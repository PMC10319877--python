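"""Shared builders for synthetic test tracks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pedtraj.records import RAW_COLUMNS, Trajectory
from pedtraj.simulate import M_PER_DEG_LAT

SCHOOL = (41.4130, 2.1870)  # the ZAF synthetic school


def make_track(
    latlon: np.ndarray,
    start: str = "2018-11-05 08:00:00",
    seconds: np.ndarray | None = None,
    nickname: str = "zaf_0001_walk_alone",
    haccuracy: float = 10.0,
) -> Trajectory:
    """Trajectory from an (n, 2) lat/lon array at 1 Hz (or given seconds)."""
    latlon = np.asarray(latlon, dtype=float)
    n = len(latlon)
    if seconds is None:
        seconds = np.arange(n)
    t = pd.Timestamp(start) + pd.to_timedelta(seconds, unit="s")
    df = pd.DataFrame(
        {
            "course": 0.0,
            "haccuracy": haccuracy,
            "latitude": latlon[:, 0],
            "longitude": latlon[:, 1],
            "speed": 0.0,
            "time": t,
            "nickname": nickname,
        }
    )[RAW_COLUMNS]
    from pedtraj.io import parse_nickname

    return Trajectory(df=df, metadata=parse_nickname(nickname))


def straight_track(
    v: float = 1.5,
    n: int = 600,
    lat0: float = 41.40,
    lon0: float = 2.00,
    heading_east: bool = True,
    **kw,
) -> Trajectory:
    """Constant-speed straight walk (eastbound by default)."""
    steps = v * np.arange(n)
    if heading_east:
        lat = np.full(n, lat0)
        lon = lon0 + steps / (M_PER_DEG_LAT * np.cos(np.radians(lat0)))
    else:
        lat = lat0 + steps / M_PER_DEG_LAT
        lon = np.full(n, lon0)
    return make_track(np.column_stack([lat, lon]), **kw)


def track_from_speeds(
    speeds: np.ndarray, lat0: float = 41.40, lon0: float = 2.00, **kw
) -> Trajectory:
    """Northbound 1 Hz track whose step velocities equal ``speeds``."""
    lat = lat0 + np.concatenate([[0.0], np.cumsum(speeds)]) / M_PER_DEG_LAT
    lon = np.full(len(lat), lon0)
    return make_track(np.column_stack([lat, lon]), **kw)


def commute_track(
    school: tuple[float, float] = SCHOOL,
    home_dist: float = 600.0,
    v: float = 1.5,
    to_school: bool = True,
    **kw,
) -> Trajectory:
    """Straight commute ending (or starting) exactly at the school."""
    n = int(home_dist / v) + 1
    offsets = home_dist - v * np.arange(n)  # meters north of school
    if not to_school:
        offsets = offsets[::-1]
    lat = school[0] + offsets / M_PER_DEG_LAT
    lon = np.full(n, school[1])
    return make_track(np.column_stack([lat, lon]), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default labelled cohort shared by the heavier tests."""
    from pedtraj.simulate import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(n_participants=8, rng_seed=11))
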