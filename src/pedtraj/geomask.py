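"""Spatial k-anonymity geomasking of trip endpoints.

The home end of a commute trace can reveal where a participant lives.
The masking step strips the first (home-to-school) or last
(school-to-home) ``t`` seconds of *movement* from each trip, with ``t``
drawn uniformly on the integers [t_min, t_max] per trajectory.

The disclosure risk of the masked endpoint is quantified through spatial
k-anonymity: assuming a constant walking speed ``v`` for everyone, the
masked endpoint is consistent with any of the ``k`` housing units inside
a circle of radius ``d = v * t``; with a district housing density
``rho`` (units/km²),

    k = rho * pi * (v * t)^2        (area in km²),

and the disclosure risk — roughly the probability of pointing at the
right home — is ``1/k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cleaning import StageReport, traj_key
from .kinematics import compute_steps, geodesic_distance
from .records import Direction, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class GeomaskPolicy:
    """Parameters of the masking and its risk model.

    v_assumed: constant walking speed (m/s) of the risk model (1.5).
    t_min, t_max: bounds (s) of the uniformly drawn masked window.
    rng_seed: seed of the per-trajectory draws.
    min_remaining_records: a trip left with fewer fixes is discarded.
    """

    v_assumed: float = 1.5
    t_min: int = 20
    t_max: int = 50
    rng_seed: int = 0
    min_remaining_records: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.t_min <= self.t_max):
            raise ValueError("need 0 < t_min <= t_max")
        if not self.v_assumed > 0:
            raise ValueError("v_assumed must be strictly positive")


@dataclass(frozen=True)
class DistrictHousing:
    """Housing stock of the zone containing one or more schools."""

    name: str
    surface: float        # km²
    housing_units: int
    school_codes: tuple[str, ...] = ()

    @property
    def density(self) -> float:
        """Housing units per km²."""
        return housing_density(self.housing_units, self.surface)


def housing_density(units: float, surface: float) -> float:
    """Housing units per km² (exact quotient)."""
    if not surface > 0:
        raise ValueError("surface must be strictly positive")
    return units / surface


def disclosure_risk(
    density: float, policy: GeomaskPolicy | None = None, t: float | None = None
) -> float:
    """Risk 1/k of identifying the home behind a masked endpoint.

    ``k`` is the number of housing units within the circle of radius
    ``d = v * t``: ``density * pi * d^2`` with the area in km².
    """
    policy = policy or GeomaskPolicy()
    t = policy.t_max if t is None else t
    if not t > 0 or not density > 0:
        raise ValueError("disclosure risk undefined for zero density or zero t")
    d_km = policy.v_assumed * t / 1000.0
    k = density * np.pi * d_km**2
    return 1.0 / k


def average_disclosure_risk(
    districts: Sequence[DistrictHousing],
    policy: GeomaskPolicy | None = None,
    t: float | None = None,
) -> float:
    """Unweighted mean of the per-district risks 1/k."""
    if not districts:
        raise ValueError("need at least one district")
    return float(
        np.mean([disclosure_risk(d.density, policy, t) for d in districts])
    )


def load_districts(path=None) -> list[DistrictHousing]:
    """Load the district housing table (name, surface_km2, housing_units,
    school_codes); defaults to the packaged table."""
    if path is None:
        with resources.as_file(
            resources.files("pedtraj.data").joinpath("districts.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        codes = tuple(
            c for c in str(row.get("school_codes", "")).split(";") if c and c != "nan"
        )
        out.append(
            DistrictHousing(
                name=str(row["district"]),
                surface=float(row["surface_km2"]),
                housing_units=int(row["housing_units"]),
                school_codes=codes,
            )
        )
    return out


def load_school_coords(path=None) -> dict[str, tuple[float, float]]:
    """Load school coordinates (code, latitude, longitude) from CSV;
    defaults to the packaged *synthetic* locations."""
    if path is None:
        with resources.as_file(
            resources.files("pedtraj.data").joinpath("schools_synthetic.csv")
        ) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return {
        str(r["code"]).upper(): (float(r["latitude"]), float(r["longitude"]))
        for _, r in df.iterrows()
    }


def infer_direction(
    traj: Trajectory, school_latlon: tuple[float, float]
) -> Direction:
    """Endpoint nearest the school is the destination: if the *last* fix
    is nearer, the trip ran home-to-school."""
    ll = traj.latlon
    lat_s, lon_s = school_latlon
    d_first = geodesic_distance(ll[0, 0], ll[0, 1], lat_s, lon_s)
    d_last = geodesic_distance(ll[-1, 0], ll[-1, 1], lat_s, lon_s)
    return Direction.HOME_TO_SCHOOL if d_last <= d_first else Direction.SCHOOL_TO_HOME


def apply_geomask(
    traj: Trajectory,
    policy: GeomaskPolicy,
    rng: np.random.Generator,
    direction: Direction | None = None,
) -> tuple[Trajectory | None, dict]:
    """Strip a ``t``-second window of movement from the home end.

    ``t`` is drawn uniformly on the integers [t_min, t_max]. The window
    is measured in *elapsed time of movement*: leading (or trailing)
    zero-velocity fixes do not start the clock but are stripped with the
    window, so the cut is always a contiguous prefix xor suffix.

    Returns ``(masked trajectory, report)``; the trajectory is ``None``
    (reason in the report) when too little of the trip would remain.
    """
    direction = direction or traj.metadata.direction
    if direction is None:
        raise ValueError(f"trajectory {traj_key(traj)}: direction unknown")
    t_draw = int(rng.integers(policy.t_min, policy.t_max + 1))
    vel = compute_steps(traj).vel
    moving = np.flatnonzero(vel > 0)
    report: dict = {"t": t_draw, "direction": direction.value}
    if len(moving) == 0:
        report["reason"] = "no_movement"
        return None, report
    times = traj.df["time"]
    if direction is Direction.HOME_TO_SCHOOL:
        t0 = times.iloc[moving[0]]
        keep = (times - t0).dt.total_seconds() >= t_draw
    else:
        # record index moving[-1] + 1 is the end of the last moving step
        t_end = times.iloc[moving[-1] + 1]
        keep = (t_end - times).dt.total_seconds() >= t_draw
    n_removed = int((~keep).sum())
    report["n_removed"] = n_removed
    if keep.sum() < policy.min_remaining_records:
        report["reason"] = "too_short_after_mask"
        return None, report
    masked = traj.replace_df(traj.df.loc[keep])
    masked.metadata = traj.metadata.with_(direction=direction)
    removed_times = times[~keep]
    report["removed_span_s"] = (
        float((removed_times.max() - removed_times.min()).total_seconds())
        if n_removed
        else 0.0
    )
    return masked, report


class GeomaskStripper(TransformerMixin, BaseEstimator):
    """Spatial k-anonymity masking stage over a trajectory cohort.

    Direction is resolved per trip from (in order) the trip metadata, an
    explicit per-school ``direction_map``, or inference from which
    endpoint sits nearest the school (requires ``school_coords``).

    After ``transform``, ``report_`` holds the stage bookkeeping and
    ``mask_report_`` the per-trajectory draws; identical ``random_state``
    gives identical masked output.
    """

    def __init__(
        self,
        t_min: int = 20,
        t_max: int = 50,
        v_assumed: float = 1.5,
        min_remaining_records: int = 30,
        random_state: int | None = 0,
        school_coords: Mapping[str, tuple[float, float]] | None = None,
        direction_map: Mapping[str, Direction] | None = None,
    ):
        self.t_min = t_min
        self.t_max = t_max
        self.v_assumed = v_assumed
        self.min_remaining_records = min_remaining_records
        self.random_state = random_state
        self.school_coords = school_coords
        self.direction_map = direction_map

    def _policy(self) -> GeomaskPolicy:
        return GeomaskPolicy(
            v_assumed=self.v_assumed,
            t_min=self.t_min,
            t_max=self.t_max,
            rng_seed=self.random_state or 0,
            min_remaining_records=self.min_remaining_records,
        )

    def fit(self, X: Sequence[Trajectory], y=None):
        self._policy()
        return self

    def _direction(self, traj: Trajectory) -> Direction:
        if traj.metadata.direction is not None:
            return traj.metadata.direction
        code = traj.metadata.school_code
        if self.direction_map and code in self.direction_map:
            return Direction(self.direction_map[code])
        if self.school_coords and code in self.school_coords:
            return infer_direction(traj, self.school_coords[code])
        raise ValueError(f"cannot resolve direction for {traj_key(traj)}")

    def transform(self, X: Sequence[Trajectory]) -> list[Trajectory]:
        policy = self._policy()
        rng = np.random.default_rng(self.random_state)
        report = StageReport(
            "geomask", {"t_min": self.t_min, "t_max": self.t_max}
        )
        mask_report: dict[str, dict] = {}
        kept: list[Trajectory] = []
        for traj in X:
            report.n_traj_in += 1
            report.n_records_in += len(traj)
            key = traj_key(traj)
            masked, info = apply_geomask(traj, policy, rng, self._direction(traj))
            mask_report[key] = info
            if masked is None:
                report.dispositions[key] = f"removed:{info['reason']}"
                continue
            report.dispositions[key] = "kept"
            report.n_traj_kept += 1
            report.n_records_kept += len(masked)
            if info["n_removed"]:
                report.removed_records[key] = traj.df.index.difference(
                    masked.df.index
                ).tolist()
            kept.append(masked)
        self.report_ = report
        self.mask_report_ = mask_report
        return kept
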