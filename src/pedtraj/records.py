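"""Core in-memory containers for GPS trips.

A trip is held as a :class:`Trajectory`: a time-sorted pandas DataFrame of
GPS fixes plus parsed trip metadata. Step quantities (time gap, step
distance, step velocity) follow the *time-advanced* convention: the value
at row ``i`` refers to the interval between fixes ``i`` and ``i + 1``, so
the last fix carries no step values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

#: column order of the raw 7-column CSV dialect
RAW_COLUMNS = ["course", "haccuracy", "latitude", "longitude", "speed", "time", "nickname"]

#: extra columns of the processed / interpolated 10-column dialects
STEP_COLUMNS = ["dt", "d", "v"]

SCHOOL_CODES = frozenset(
    {"OAK", "VER", "VIR", "SAN", "IPC", "BEL", "MON", "ZAF", "IFT", "SGV"}
)


class Mode(str, enum.Enum):
    """Means of transport declared in the nickname."""

    WALK = "walk"
    BUS = "bus"
    CAR = "car"
    SCOOTER = "scooter"
    BIKE = "bike"
    METRO = "metro"
    TRAIN = "train"
    UNKNOWN = "unknown"


#: transport modes that disqualify a trip from the pedestrian cohort
NON_PEDESTRIAN_MODES = frozenset(
    {Mode.BUS, Mode.CAR, Mode.SCOOTER, Mode.BIKE, Mode.METRO, Mode.TRAIN}
)


class Companionship(str, enum.Enum):
    ALONE = "alone"
    ACCOMPANIED = "accompanied"
    UNKNOWN = "unknown"


class Direction(str, enum.Enum):
    HOME_TO_SCHOOL = "home_to_school"
    SCHOOL_TO_HOME = "school_to_home"


class GpsRecord(NamedTuple):
    """One timestamped GPS fix."""

    time: pd.Timestamp
    latitude: float
    longitude: float
    haccuracy: float
    course: float
    device_speed: float
    nickname: str


@dataclass(frozen=True)
class TripMetadata:
    """Trip attributes parsed from the nickname / filename conventions."""

    school_code: str | None = None
    participant_number: str | None = None
    mode: Mode = Mode.UNKNOWN
    companionship: Companionship = Companionship.UNKNOWN
    trip_date: pd.Timestamp | None = None
    direction: Direction | None = None

    @property
    def school_matched(self) -> bool:
        return self.school_code in SCHOOL_CODES

    def with_(self, **kwargs) -> "TripMetadata":
        return replace(self, **kwargs)


@dataclass
class StepSeries:
    """Per-step kinematics aligned with the fixes of one trajectory.

    Arrays have length ``n - 1`` for ``n`` fixes (index ``i`` pairs fixes
    ``i`` and ``i + 1``); the last fix has no step entry.
    """

    dt: np.ndarray   # seconds, > 0
    dist: np.ndarray  # meters, >= 0
    vel: np.ndarray  # m/s, dist / dt

    def __len__(self) -> int:
        return len(self.dt)


@dataclass
class Trajectory:
    """One trip: time-ordered GPS fixes + metadata.

    ``df`` holds the raw columns (:data:`RAW_COLUMNS`); its integer index
    is stable through cleaning (stages only delete rows, never permute),
    so row labels identify records back to the source file.
    """

    df: pd.DataFrame
    metadata: TripMetadata = field(default_factory=TripMetadata)
    source_filename: str = ""
    steps: StepSeries | None = None

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValueError("a Trajectory needs at least one record")
        t = self.df["time"]
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("records must be strictly increasing in time")
        nick = self.df["nickname"]
        if nick.nunique() > 1:
            raise ValueError("all records of one trajectory must share a nickname")

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def nickname(self) -> str:
        return str(self.df["nickname"].iloc[0])

    @property
    def times(self) -> pd.Series:
        return self.df["time"]

    @property
    def latlon(self) -> np.ndarray:
        """(n, 2) array of latitude, longitude in degrees."""
        return self.df[["latitude", "longitude"]].to_numpy(float)

    def record(self, i: int) -> GpsRecord:
        row = self.df.iloc[i]
        return GpsRecord(
            time=row["time"],
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            haccuracy=float(row["haccuracy"]),
            course=float(row["course"]),
            device_speed=float(row["speed"]),
            nickname=str(row["nickname"]),
        )

    def replace_df(self, df: pd.DataFrame) -> "Trajectory":
        """New Trajectory with the same metadata and a different fix table."""
        return Trajectory(
            df=df, metadata=self.metadata, source_filename=self.source_filename
        )


@dataclass(frozen=True)
class TrajectorySummary:
    """Trip-level movement summary.

    D: total path distance (m), the sum of step distances.
    T: trip duration (s), the sum of step time gaps (equals last - first
       timestamp).
    v_eff: effective speed D / T (m/s), a trip-level average.
    v_m: mean instantaneous step velocity (m/s), the normaliser of the
       log-velocity u = ln(v / v_m).
    """

    D: float
    T: float
    v_eff: float
    v_m: float
    n_records: int
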