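"""Reading and writing the trip CSV dialects and naming conventions.

Three dialects exist:

``raw``
    the 7 columns collected by the app
    (course, haccuracy, latitude, longitude, speed, time, nickname);
``processed``
    the cleaned/geomasked files: the raw columns plus the time-advanced
    step columns ``dt``, ``d``, ``v`` (empty on the last row);
``interpolated``
    same layout as ``processed`` but uniformly resampled to 1 Hz, so
    ``dt`` is always 1.0 and ``d`` equals ``v``.

Filenames follow ``DATE_NICKNAME[_processed|_interpolated].csv``; the
nickname encodes school code, participant number, transport mode and
companionship, e.g. ``ZAF_0001_WALK_ALONE`` or ``zaf_0067_peu``.
"""

from __future__ import annotations

import io as _io
import json
import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .records import (
    RAW_COLUMNS,
    SCHOOL_CODES,
    STEP_COLUMNS,
    Companionship,
    Mode,
    StepSeries,
    Trajectory,
    TripMetadata,
)

logger = logging.getLogger(__name__)

DIALECTS = ("raw", "processed", "interpolated")
TIME_FORMAT = "%Y-%m-%d %H:%M:%S"

_DATE_RE = re.compile(r"^(\d{4}-\d{2}-\d{2})_(.+?)(_processed|_interpolated)?$")

# fixed per-column formats so writing is reproducible byte-for-byte
_FLOAT_FMT = {
    "course": "%.6f",
    "haccuracy": "%.1f",
    "latitude": "%.6f",   # 6 dp ~ 0.11 m, the precision of the shared files
    "longitude": "%.6f",
    "speed": "%.6f",
    "dt": "%.1f",
    "d": "%.6f",
    "v": "%.6f",
}


def _load_synonyms() -> tuple[dict[str, Mode], dict[str, Companionship]]:
    text = resources.files("pedtraj.data").joinpath("mode_synonyms.yaml").read_text()
    raw = yaml.safe_load(text)
    modes = {
        syn.lower(): Mode(mode)
        for mode, syns in raw["modes"].items()
        for syn in syns
    }
    comps = {
        syn.lower(): Companionship(comp)
        for comp, syns in raw["companionship"].items()
        for syn in syns
    }
    return modes, comps


_MODE_SYNONYMS, _COMPANION_SYNONYMS = _load_synonyms()


def parse_nickname(nickname: str) -> TripMetadata:
    """Parse a participant nickname into trip metadata.

    Total on arbitrary strings: unrecognised tokens fall back to
    ``unknown`` placeholders and an unmatched school code is flagged via
    ``TripMetadata.school_matched`` (the trip is then routed to manual
    review, never dropped here).
    """
    tokens = [t for t in str(nickname).strip().split("_") if t]
    school: str | None = None
    number: str | None = None
    mode = Mode.UNKNOWN
    comp = Companionship.UNKNOWN
    if tokens:
        school = tokens[0].upper()
    for tok in tokens[1:]:
        low = tok.lower()
        if number is None and tok.isdigit():
            number = tok
        elif mode is Mode.UNKNOWN and low in _MODE_SYNONYMS:
            mode = _MODE_SYNONYMS[low]
        elif comp is Companionship.UNKNOWN and low in _COMPANION_SYNONYMS:
            comp = _COMPANION_SYNONYMS[low]
    if school is not None and school not in SCHOOL_CODES:
        logger.debug("nickname %r: school code %r not recognised", nickname, school)
    return TripMetadata(
        school_code=school, participant_number=number, mode=mode, companionship=comp
    )


def parse_filename(filename: str) -> tuple[pd.Timestamp, TripMetadata, str]:
    """Split ``DATE_NICKNAME[_suffix].csv`` into date, metadata and dialect.

    Returns ``(trip_date, metadata, dialect)`` where dialect is one of
    ``raw`` / ``processed`` / ``interpolated``.

    Raises ``ValueError`` naming the file when the leading ISO date is
    missing.
    """
    stem = Path(filename).name
    if stem.endswith(".csv"):
        stem = stem[:-4]
    m = _DATE_RE.match(stem)
    if m is None:
        raise ValueError(f"filename {filename!r} lacks the leading YYYY-MM-DD date")
    date = pd.Timestamp(m.group(1))
    dialect = (m.group(3) or "_raw").lstrip("_")
    meta = parse_nickname(m.group(2)).with_(trip_date=date)
    return date, meta, dialect


def trajectory_filename(traj: Trajectory, dialect: str = "raw") -> str:
    """Protocol-compliant filename for a trajectory."""
    date = traj.metadata.trip_date
    if date is None:
        date = traj.df["time"].iloc[0].normalize()
    suffix = "" if dialect == "raw" else f"_{dialect}"
    return f"{date.strftime('%Y-%m-%d')}_{traj.nickname.lower()}{suffix}.csv"


def _parse_times(col: pd.Series) -> pd.Series:
    # naive local wall-clock, 1 s resolution; tolerate the colon-separated
    # date variant some exports use
    try:
        return pd.to_datetime(col, format=TIME_FORMAT)
    except ValueError:
        return pd.to_datetime(col, format="%Y:%m:%d %H:%M:%S")


def read_trajectory(
    path,
    dialect: str = "auto",
    *,
    decimal: str = ".",
) -> Trajectory:
    """Read one trip CSV into a :class:`Trajectory`.

    Records are time-sorted; duplicate timestamps keep the first
    occurrence and out-of-range coordinates are rejected, both logged.
    Files with or without a header row are accepted. For the 10-column
    dialects the derived step columns are loaded into ``traj.steps``
    (they remain recomputable from the fixes).
    """
    path = Path(path)
    if dialect == "auto":
        try:
            _, _, dialect = parse_filename(path.name)
        except ValueError:
            dialect = "raw"
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = 7 if dialect == "raw" else 10
    names = RAW_COLUMNS if ncols == 7 else RAW_COLUMNS + STEP_COLUMNS

    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        fh.seek(0)
        has_header = "latitude" in first.lower()
        df = pd.read_csv(
            fh,
            header=0 if has_header else None,
            names=names,
            decimal=decimal,
            skipinitialspace=True,
        )
    if df.shape[1] != ncols:
        raise ValueError(
            f"{path.name}: expected {ncols} columns for {dialect} dialect, "
            f"got {df.shape[1]}"
        )
    df["time"] = _parse_times(df["time"])

    bad = ~(
        df["latitude"].between(-90.0, 90.0)
        & df["longitude"].between(-180.0, 180.0)
        & (df["haccuracy"] >= 0.0)
    )
    if bad.any():
        logger.warning("%s: rejected %d out-of-range records", path.name, int(bad.sum()))
        df = df[~bad]
    df = df.sort_values("time", kind="stable")
    dup = df["time"].duplicated()
    if dup.any():
        logger.warning("%s: dropped %d duplicate timestamps", path.name, int(dup.sum()))
        df = df[~dup]
    df = df.reset_index(drop=True)

    steps = None
    if ncols == 10 and len(df) >= 2:
        steps = StepSeries(
            dt=df["dt"].to_numpy(float)[:-1],
            dist=df["d"].to_numpy(float)[:-1],
            vel=df["v"].to_numpy(float)[:-1],
        )
    try:
        _, meta, _ = parse_filename(path.name)
    except ValueError:
        meta = parse_nickname(str(df["nickname"].iloc[0]))
    return Trajectory(
        df=df[RAW_COLUMNS], metadata=meta, source_filename=path.name, steps=steps
    )


def write_trajectory(traj: Trajectory, path, dialect: str = "raw") -> None:
    """Write a trip in the requested dialect.

    Column order is fixed (course, haccuracy, latitude, longitude, speed,
    time, nickname[, dt, d, v]); timestamps are ``YYYY-MM-DD HH:MM:SS``;
    coordinates are written at 6 decimal places. For the 10-column
    dialects the step series must be attached and the last row's derived
    fields are left empty (time-advanced convention).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(traj.df) == 0:
        raise ValueError("refusing to write an empty trajectory")
    out = traj.df[RAW_COLUMNS].copy()
    cols = list(RAW_COLUMNS)
    if dialect != "raw":
        if traj.steps is None:
            raise ValueError(
                f"{dialect} dialect needs an attached StepSeries; "
                "run kinematics.compute_steps first"
            )
        if len(traj.steps) != len(out) - 1:
            raise ValueError("StepSeries length does not match record count")
        for name, arr in zip(STEP_COLUMNS, (traj.steps.dt, traj.steps.dist, traj.steps.vel)):
            out[name] = np.append(arr.astype(float), np.nan)
        cols += STEP_COLUMNS

    buf = _io.StringIO()
    buf.write(",".join(cols) + "\n")
    times = out["time"].dt.strftime(TIME_FORMAT).to_numpy()
    formatted = {
        c: [(_FLOAT_FMT[c] % x) if np.isfinite(x) else "" for x in out[c].to_numpy(float)]
        for c in cols
        if c not in ("time", "nickname")
    }
    nick = out["nickname"].astype(str).to_numpy()
    for i in range(len(out)):
        row = [
            times[i] if c == "time" else nick[i] if c == "nickname" else formatted[c][i]
            for c in cols
        ]
        buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def to_geojson(trajectories: Iterable[Trajectory], path) -> None:
    """Export trips as a GeoJSON FeatureCollection (one LineString each)."""
    features = []
    for traj in trajectories:
        coords = [[round(lon, 6), round(lat, 6)] for lat, lon in traj.latlon]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "nickname": traj.nickname,
                    "school": traj.metadata.school_code,
                    "mode": traj.metadata.mode.value,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}), encoding="utf-8"
    )
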