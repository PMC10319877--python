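"""Cleaning stages 1-3: non-pedestrian removal, origin-destination
validation, outlier clean-up.

Each stage is a scikit-learn style transformer over a list of
:class:`~pedtraj.records.Trajectory`: ``fit`` validates parameters and
returns ``self``; ``transform`` returns the kept trajectories and leaves
a :class:`StageReport` in ``report_``. Stages only delete records, never
permute them, so the DataFrame row labels survive and identify every
removed record back to the source file.

Because the original study applied these steps by inspecting routes on
maps, every threshold here is explicit and overridable; the defaults are
chosen to sit just outside the kept pedestrian data's plausible range
(e.g. a 10 m/s instantaneous cap is above any running teenager but far
below the ~90 m/s GPS activation spikes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .kinematics import compute_steps, geodesic_distance, summarize
from .records import Mode, NON_PEDESTRIAN_MODES, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class CleaningPolicy:
    """Thresholds for the cleaning stages (all strictly positive).

    v_nonped: v_eff cap (m/s) above which an unknown-mode trip is treated
        as an unlabelled vehicle.
    v_outlier_max: instantaneous velocity cap (m/s) for outlier records.
    haccuracy_max: maximum tolerated GPS uncertainty radius (m).
    school_radius: distance (m) within which an endpoint counts as "at
        school" (protocol: recording starts/stops 5-150 m from home).
    min_records: minimum fixes for a meaningful trip.
    max_outlier_fraction: removed-record fraction above which the whole
        trip is discarded.
    endpoint_dwell_radius / endpoint_dwell_min: a terminal cluster of
        fixes within this radius (m) of the final position lasting longer
        than this (s) is collapsed to its first record (GPS accumulating
        indoors at the school).
    """

    v_nonped: float = 2.5
    v_outlier_max: float = 10.0
    haccuracy_max: float = 100.0
    school_radius: float = 150.0
    min_records: int = 30
    max_outlier_fraction: float = 0.3
    endpoint_dwell_radius: float = 20.0
    endpoint_dwell_min: float = 60.0

    def __post_init__(self) -> None:
        for name, val in vars(self).items():
            if not val > 0:
                raise ValueError(f"CleaningPolicy.{name} must be strictly positive")


@dataclass
class StageReport:
    """Bookkeeping for one cleaning stage.

    Satisfies the identity ``n_records_in == n_records_kept +
    n_records_removed`` and gives every input trajectory a disposition
    (``kept`` / ``removed:<reason>`` / ``review:<reason>``).
    """

    stage: str
    thresholds: dict = field(default_factory=dict)
    n_traj_in: int = 0
    n_traj_kept: int = 0
    n_records_in: int = 0
    n_records_kept: int = 0
    dispositions: dict[str, str] = field(default_factory=dict)
    #: row labels removed from trajectories that were themselves kept
    removed_records: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_traj_removed(self) -> int:
        return self.n_traj_in - self.n_traj_kept

    @property
    def n_records_removed(self) -> int:
        return self.n_records_in - self.n_records_kept

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "thresholds": self.thresholds,
            "trajectories": {
                "in": self.n_traj_in,
                "kept": self.n_traj_kept,
                "removed": self.n_traj_removed,
            },
            "records": {
                "in": self.n_records_in,
                "kept": self.n_records_kept,
                "removed": self.n_records_removed,
            },
            "dispositions": self.dispositions,
        }


def traj_key(traj: Trajectory) -> str:
    """Stable identifier of a trajectory within a cohort."""
    return traj.source_filename or traj.nickname


# ---------------------------------------------------------------------------
# stage 1: non-pedestrian removal


class NonPedestrianFilter(TransformerMixin, BaseEstimator):
    """Drop trips made by a declared non-walking mode, and unknown-mode
    trips whose effective speed is not plausibly pedestrian.

    Parameters
    ----------
    v_nonped : float
        v_eff threshold (m/s) applied only when the declared mode is
        unknown; walkers are kept regardless of their speed.
    """

    def __init__(self, v_nonped: float = 2.5):
        self.v_nonped = v_nonped

    def fit(self, X: Sequence[Trajectory], y=None):
        if not self.v_nonped > 0:
            raise ValueError("v_nonped must be strictly positive")
        return self

    def transform(self, X: Sequence[Trajectory]) -> list[Trajectory]:
        report = StageReport("non_pedestrian", {"v_nonped": self.v_nonped})
        kept: list[Trajectory] = []
        for traj in X:
            report.n_traj_in += 1
            report.n_records_in += len(traj)
            key = traj_key(traj)
            mode = traj.metadata.mode
            if mode in NON_PEDESTRIAN_MODES:
                report.dispositions[key] = f"removed:mode={mode.value}"
                continue
            if mode is Mode.UNKNOWN:
                v_eff = summarize(traj).v_eff if len(traj) > 1 else 0.0
                if v_eff > self.v_nonped:
                    report.dispositions[key] = "removed:abnormal_velocity"
                    continue
            report.dispositions[key] = "kept"
            report.n_traj_kept += 1
            report.n_records_kept += len(traj)
            kept.append(traj)
        self.report_ = report
        return kept


# ---------------------------------------------------------------------------
# stage 2: invalid / non-origin-destination trajectories


def validate_origin_destination(
    traj: Trajectory,
    school_latlon: tuple[float, float],
    policy: CleaningPolicy | None = None,
) -> tuple[bool, str]:
    """Check that a trip is a well-defined school commute.

    Valid iff (a) exactly one endpoint lies within ``school_radius`` of
    the school (the other end is the home side), (b) the trip has at
    least ``min_records`` fixes, and (c) the net displacement is at least
    twice the school radius — which rejects clouds of fixes scattered
    around the school.
    """
    policy = policy or CleaningPolicy()
    lat_s, lon_s = school_latlon
    ll = traj.latlon
    d_first = geodesic_distance(ll[0, 0], ll[0, 1], lat_s, lon_s)
    d_last = geodesic_distance(ll[-1, 0], ll[-1, 1], lat_s, lon_s)
    at_school = (d_first <= policy.school_radius, d_last <= policy.school_radius)
    if len(traj) < policy.min_records:
        return False, "too_few_records"
    if not any(at_school):
        return False, "no_school_endpoint"
    if all(at_school):
        return False, "scatter_around_school"
    net = geodesic_distance(ll[0, 0], ll[0, 1], ll[-1, 0], ll[-1, 1])
    if net < 2.0 * policy.school_radius:
        return False, "short_displacement"
    return True, "ok"


class OriginDestinationValidator(TransformerMixin, BaseEstimator):
    """Keep only trips with one endpoint at the school and a real
    displacement away from it.

    Trajectories whose school code is not one of the known codes are
    routed to ``review_`` (manual-review list) rather than silently
    dropped; a *known* code missing from ``school_coords`` raises.
    """

    def __init__(
        self,
        school_coords: Mapping[str, tuple[float, float]] | None = None,
        school_radius: float = 150.0,
        min_records: int = 30,
    ):
        self.school_coords = school_coords
        self.school_radius = school_radius
        self.min_records = min_records

    def _policy(self) -> CleaningPolicy:
        return CleaningPolicy(
            school_radius=self.school_radius, min_records=self.min_records
        )

    def fit(self, X: Sequence[Trajectory], y=None):
        self._policy()
        if not self.school_coords:
            raise ValueError("school_coords mapping is required")
        return self

    def transform(self, X: Sequence[Trajectory]) -> list[Trajectory]:
        policy = self._policy()
        report = StageReport(
            "origin_destination",
            {"school_radius": self.school_radius, "min_records": self.min_records},
        )
        kept: list[Trajectory] = []
        review: list[Trajectory] = []
        for traj in X:
            report.n_traj_in += 1
            report.n_records_in += len(traj)
            key = traj_key(traj)
            code = traj.metadata.school_code
            if not traj.metadata.school_matched:
                report.dispositions[key] = "review:unmatched_school"
                review.append(traj)
                continue
            if code not in self.school_coords:
                raise KeyError(f"no coordinates supplied for school {code!r}")
            ok, reason = validate_origin_destination(
                traj, self.school_coords[code], policy
            )
            if ok:
                report.dispositions[key] = "kept"
                report.n_traj_kept += 1
                report.n_records_kept += len(traj)
                kept.append(traj)
            else:
                report.dispositions[key] = f"removed:{reason}"
        self.report_ = report
        self.review_ = review
        return kept


# ---------------------------------------------------------------------------
# stage 3: outlier records and whole-trajectory discard


def _flag_outlier_records(traj: Trajectory, policy: CleaningPolicy) -> np.ndarray:
    """Boolean mask of records implicated in velocity/accuracy outliers.

    A record is velocity-implicated when *both* its incoming and outgoing
    step velocities exceed the cap, or it is terminal with its single
    adjacent step exceeding — this spares the good neighbour of a spike.
    """
    n = len(traj)
    bad = traj.df["haccuracy"].to_numpy(float) > policy.haccuracy_max
    if n < 2:
        return bad
    vel = compute_steps(traj).vel
    over = vel > policy.v_outlier_max
    vbad = np.zeros(n, dtype=bool)
    vbad[0] = over[0]
    vbad[-1] = over[-1]
    if n > 2:
        vbad[1:-1] = over[:-1] & over[1:]
    return bad | vbad


def remove_outliers(
    traj: Trajectory, policy: CleaningPolicy | None = None
) -> tuple[Trajectory | None, dict]:
    """Clean one trip of outlier records; discard it if too corrupted.

    Iterates flag-and-drop passes to a fixed point (a single pass would
    mislabel the record after a spike), then collapses a terminal dwell
    cluster to its first fix. If the removed fraction exceeds
    ``max_outlier_fraction`` no meaningful origin-destination trip
    remains and ``None`` is returned.
    """
    policy = policy or CleaningPolicy()
    n0 = len(traj)
    current = traj
    removed: list[int] = []
    for _ in range(10):  # fixed-point iteration cap
        mask = _flag_outlier_records(current, policy)
        if not mask.any():
            break
        removed.extend(current.df.index[mask].tolist())
        df = current.df.loc[~mask]
        if len(df) < 2:
            return None, {"removed": removed + df.index.tolist(), "reason": "all_outliers"}
        current = current.replace_df(df)

    # the discard rule gauges path corruption, so only spike/accuracy
    # removals count toward it — the dwell trim below is a benign cut
    frac = len(removed) / n0

    # terminal dwell: contiguous tail within dwell_radius of the final fix
    ll = current.latlon
    d_to_end = geodesic_distance(ll[:, 0], ll[:, 1], ll[-1, 0], ll[-1, 1])
    j = len(current) - 1
    while j > 0 and d_to_end[j - 1] <= policy.endpoint_dwell_radius:
        j -= 1
    t = current.df["time"]
    if j < len(current) - 1:
        dwell_span = (t.iloc[-1] - t.iloc[j]).total_seconds()
        if dwell_span > policy.endpoint_dwell_min:
            drop = current.df.index[j + 1 :]
            removed.extend(drop.tolist())
            current = current.replace_df(current.df.iloc[: j + 1])

    info = {"removed": removed, "removed_fraction": frac, "reason": None}
    if frac > policy.max_outlier_fraction:
        info["reason"] = "too_many_outliers"
        return None, info
    return current, info


class OutlierRemover(TransformerMixin, BaseEstimator):
    """Strip velocity/accuracy outliers and terminal dwell clusters;
    discard trips where the removed fraction is too high."""

    def __init__(
        self,
        v_outlier_max: float = 10.0,
        haccuracy_max: float = 100.0,
        max_outlier_fraction: float = 0.3,
        endpoint_dwell_radius: float = 20.0,
        endpoint_dwell_min: float = 60.0,
    ):
        self.v_outlier_max = v_outlier_max
        self.haccuracy_max = haccuracy_max
        self.max_outlier_fraction = max_outlier_fraction
        self.endpoint_dwell_radius = endpoint_dwell_radius
        self.endpoint_dwell_min = endpoint_dwell_min

    def _policy(self) -> CleaningPolicy:
        return CleaningPolicy(
            v_outlier_max=self.v_outlier_max,
            haccuracy_max=self.haccuracy_max,
            max_outlier_fraction=self.max_outlier_fraction,
            endpoint_dwell_radius=self.endpoint_dwell_radius,
            endpoint_dwell_min=self.endpoint_dwell_min,
        )

    def fit(self, X: Sequence[Trajectory], y=None):
        self._policy()
        return self

    def transform(self, X: Sequence[Trajectory]) -> list[Trajectory]:
        policy = self._policy()
        report = StageReport(
            "outliers",
            {
                "v_outlier_max": self.v_outlier_max,
                "haccuracy_max": self.haccuracy_max,
                "max_outlier_fraction": self.max_outlier_fraction,
            },
        )
        kept: list[Trajectory] = []
        for traj in X:
            report.n_traj_in += 1
            report.n_records_in += len(traj)
            key = traj_key(traj)
            cleaned, info = remove_outliers(traj, policy)
            if cleaned is None:
                report.dispositions[key] = f"removed:{info['reason']}"
                continue
            report.dispositions[key] = "kept"
            report.n_traj_kept += 1
            report.n_records_kept += len(cleaned)
            if info["removed"]:
                report.removed_records[key] = info["removed"]
            kept.append(cleaned)
        self.report_ = report
        return kept


def filter_non_pedestrian(
    trajectories: Sequence[Trajectory], policy: CleaningPolicy | None = None
) -> tuple[list[Trajectory], list[Trajectory], StageReport]:
    """Functional wrapper over :class:`NonPedestrianFilter`."""
    policy = policy or CleaningPolicy()
    step = NonPedestrianFilter(v_nonped=policy.v_nonped).fit(trajectories)
    kept = step.transform(trajectories)
    kept_keys = {traj_key(t) for t in kept}
    removed = [t for t in trajectories if traj_key(t) not in kept_keys]
    return kept, removed, step.report_
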