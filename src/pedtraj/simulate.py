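"""Synthetic school-commute GPS cohorts with ground-truth labels.

The generator emits raw-dialect trajectories with the statistical
structure the cleaning pipeline assumes, so every stage is testable
without any collected data:

* walking trips from a home point (drawn in an annulus around the
  school, never emitted) to the school along an abstract street lattice,
  sampled at 1 Hz with per-second lognormal speed variation around a
  per-trip base speed;
* a gap model thinning the 1 Hz series (17% of steps longer than 1 s,
  99.8% of steps at most 4 s);
* AR(1)-correlated GPS position noise — receiver error at 1 Hz is
  strongly autocorrelated, and white noise of realistic amplitude would
  swamp step velocities;
* injected artifacts: startup outlier bursts (jump speeds 20-90 m/s),
  terminal dwell clusters at the school, and contaminant trips
  (declared non-pedestrian modes, unlabelled vehicles, scatter blobs
  around the school, trips with no school endpoint).

Every record and trajectory carries a truth label in the returned
:class:`TruthLedger`, so stage-by-stage precision/recall of the pipeline
can be scored exactly (:func:`truth_eval`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cleaning import StageReport
from .geomask import load_school_coords
from .io import parse_nickname, trajectory_filename, write_trajectory
from .kinematics import EARTH_RADIUS_M
from .records import Direction, RAW_COLUMNS, Trajectory, TripMetadata

logger = logging.getLogger(__name__)

M_PER_DEG_LAT = EARTH_RADIUS_M * np.pi / 180.0

PEDESTRIAN = "pedestrian"
MODE_CONTAMINANT = "mode_contaminant"
UNLABELED_VEHICLE = "unlabeled_vehicle"
SCATTER = "scatter"
NO_OD = "no_od"

CONTAMINANT_CLASSES = (MODE_CONTAMINANT, UNLABELED_VEHICLE, SCATTER, NO_OD)


@dataclass
class CohortSpec:
    """Study conditions of a simulated cohort.

    Walking speeds: per-trip base speed lognormal with mean
    ``speed_mean`` = 1.5 m/s and sd ``speed_sd`` = 0.25 across trips
    (matching the spread of effective speeds in kept commutes), with
    per-second multiplicative variation of cv ``step_speed_cv``.
    Durations uniform on [300, 700] s (bracketing the observed
    quartiles). The gap model gives P(dt > 1 s) = 0.17 split as
    ``gap_probs`` with P(dt <= 4 s) = 0.998.
    """

    school_codes: tuple[str, ...] = (
        "OAK", "VER", "VIR", "SAN", "IPC", "BEL", "MON", "ZAF", "IFT", "SGV",
    )
    n_participants: int = 8            # per school
    school_coords: Mapping[str, tuple[float, float]] | None = None
    speed_mean: float = 1.5            # m/s, cohort mean of per-trip base speed
    speed_sd: float = 0.25             # m/s, across trips
    step_speed_cv: float = 0.3         # within-trip per-second cv
    duration_min: float = 300.0        # s
    duration_max: float = 700.0
    #: unconditional P(dt = g) for gaps g > 1 s; remaining mass is dt = 1 s
    gap_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.10, 3: 0.05, 4: 0.018, 6: 0.002}
    )
    noise_sd: float = 3.0              # m per axis, stationary
    noise_rho: float = 0.998           # AR(1) coefficient at 1 s
    p_outlier_burst: float = 0.3       # per pedestrian trip
    burst_max_records: int = 6
    burst_speed: tuple[float, float] = (20.0, 90.0)  # m/s jump range
    p_dwell: float = 0.3
    dwell_duration: tuple[float, float] = (90.0, 180.0)  # s
    dwell_jitter: float = 3.0          # m
    p_mode_missing: float = 0.1        # pedestrians without a mode token
    frac_mode_contaminant: float = 0.10
    frac_unlabeled_vehicle: float = 0.05
    frac_scatter: float = 0.05
    frac_no_od: float = 0.05
    #: home annulus around the school; the lower bound stays above the
    #: OD-validation displacement rule (2 x school_radius) plus the worst
    #: startup-burst offset, so genuine commutes are never border cases
    home_dist_min: float = 400.0       # m
    home_dist_max: float = 1500.0
    school_radius: float = 150.0       # m, the OD-validation radius
    start_date: str = "2018-11-05"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_outlier_burst", "p_dwell", "p_mode_missing",
            "frac_mode_contaminant", "frac_unlabeled_vehicle",
            "frac_scatter", "frac_no_od",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"CohortSpec.{name} must be a probability")
        if sum(self.gap_probs.values()) > 1.0:
            raise ValueError("gap probabilities exceed 1")
        if self.home_dist_min <= self.school_radius:
            raise ValueError(
                "infeasible spec: home annulus starts inside the school radius"
            )
        total_contam = (
            self.frac_mode_contaminant + self.frac_unlabeled_vehicle
            + self.frac_scatter + self.frac_no_od
        )
        if total_contam > 1.0:
            raise ValueError("contamination fractions exceed 1")

    def clean(self) -> "CohortSpec":
        """Copy of the spec with no noise, gaps, artifacts or contaminants
        and complete mode labelling (every generated trip passes all
        cleaning stages untouched — an unlabelled fast walker would
        otherwise trip the unknown-mode speed rule)."""
        return replace(
            self,
            gap_probs={},
            noise_sd=0.0,
            p_outlier_burst=0.0,
            p_dwell=0.0,
            p_mode_missing=0.0,
            frac_mode_contaminant=0.0,
            frac_unlabeled_vehicle=0.0,
            frac_scatter=0.0,
            frac_no_od=0.0,
        )


@dataclass
class TrajTruth:
    """Ground truth for one generated trajectory."""

    key: str                   # source filename
    school: str
    cls: str                   # pedestrian / contaminant class
    direction: str | None
    mode_token: str | None
    n_records: int
    record_labels: list[str]   # clean / outlier / dwell, in written row order
    gap_extra_seconds: int     # sum(dt - 1) over the written record sequence
    base_speed: float | None = None


@dataclass
class TruthLedger:
    trajectories: dict[str, TrajTruth] = field(default_factory=dict)

    def of_class(self, *classes: str) -> list[str]:
        return [k for k, t in self.trajectories.items() if t.cls in classes]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({k: asdict(v) for k, v in self.trajectories.items()}),
            encoding="utf-8",
        )


# ---------------------------------------------------------------------------
# geometry helpers (local east/north meters around the school)


def _enu_to_latlon(xy: np.ndarray, school: tuple[float, float]) -> np.ndarray:
    lat0, lon0 = school
    lat = lat0 + xy[:, 1] / M_PER_DEG_LAT
    lon = lon0 + xy[:, 0] / (M_PER_DEG_LAT * np.cos(np.radians(lat0)))
    return np.column_stack([lat, lon])


def _grid_route(
    rng: np.random.Generator,
    length: float,
    disp_min: float,
    disp_max: float,
) -> np.ndarray:
    """Path of (approximately) the given arc length along an abstract
    street lattice, from the school (origin) to an endpoint whose
    straight-line distance lies in [disp_min, disp_max].

    The endpoint is drawn first, a Manhattan staircase of 40-120 m
    blocks is laid toward it, and leftover length is spent on detour
    jogs (up a side street and back), which preserves the turn structure
    a grid commute has.
    """
    disp_hi = min(disp_max, 0.95 * length)
    if disp_hi < disp_min:
        raise ValueError("route length too short to reach the endpoint annulus")
    disp = rng.uniform(disp_min, disp_hi)
    # bearing within the lattice quadrant, restricted so the Manhattan
    # distance |a| + |b| = disp (cos b + sin b) fits inside the length
    m = length / disp
    beta_max = np.pi / 4.0 if m >= np.sqrt(2.0) else np.arcsin(m / np.sqrt(2.0)) - np.pi / 4.0
    beta = rng.uniform(0.0, max(beta_max * 0.95, 1e-3))
    axis = int(rng.integers(4))  # which lattice semi-axis the route hugs
    theta = rng.uniform(0.0, 90.0)
    u1 = np.array([np.cos(np.radians(theta + 90.0 * axis)),
                   np.sin(np.radians(theta + 90.0 * axis))])
    u2 = np.array([-u1[1], u1[0]]) * (1.0 if rng.random() < 0.5 else -1.0)
    a = disp * np.cos(beta)   # along-axis component
    b = disp * np.sin(beta)   # cross-axis component

    def _split(total: float, direction: np.ndarray) -> list[np.ndarray]:
        moves = []
        left = total
        while left > 0:
            seg = min(rng.uniform(40.0, 120.0), left)
            moves.append(direction * seg)
            left -= seg
        return moves

    moves = _split(a, u1) + _split(b, u2)
    order = rng.permutation(len(moves))
    moves = [moves[i] for i in order]
    extra = length - (a + b)
    while extra > 20.0:
        s = min(rng.uniform(30.0, 60.0), extra / 2.0)
        j = int(rng.integers(len(moves) + 1))
        jog = u2 * s * (1.0 if rng.random() < 0.5 else -1.0)
        moves[j:j] = [jog, -jog]
        extra -= 2.0 * s
    pts = np.vstack([np.zeros(2), np.cumsum(moves, axis=0)])
    return pts


def _walk_positions(
    rng: np.random.Generator,
    path: np.ndarray,
    base_speed: float,
    cv: float,
) -> np.ndarray:
    """1 Hz positions walking the path from its far end (home) to the
    school at per-second lognormal speeds."""
    seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    L = cum[-1]
    sigma = np.sqrt(np.log1p(cv**2))
    speeds = []
    covered = 0.0
    while covered < L:
        s = base_speed * rng.lognormal(-sigma**2 / 2.0, sigma)
        speeds.append(s)
        covered += s
    arc = L - np.concatenate([[0.0], np.cumsum(speeds)])
    arc = np.clip(arc, 0.0, L)
    x = np.interp(arc, cum, path[:, 0])
    y = np.interp(arc, cum, path[:, 1])
    return np.column_stack([x, y])


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    if sd <= 0.0:
        return np.zeros((n, 2))
    e = np.zeros((n, 2))
    e[0] = rng.normal(0.0, sd, 2)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), (n - 1, 2))
    for i in range(1, n):
        e[i] = rho * e[i - 1] + innov[i - 1]
    return e


def _sample_gaps(rng: np.random.Generator, spec: CohortSpec, n_seconds: int) -> np.ndarray:
    """Indices (seconds) kept by the gap model, always including 0 and the
    final second."""
    gaps = sorted(spec.gap_probs)
    probs = np.array([spec.gap_probs[g] for g in gaps])
    p1 = 1.0 - probs.sum()
    choices = np.array([1] + list(gaps))
    pvals = np.concatenate([[p1], probs])
    idx = [0]
    while idx[-1] < n_seconds - 1:
        step = int(rng.choice(choices, p=pvals))
        idx.append(min(idx[-1] + step, n_seconds - 1))
    return np.asarray(idx)


def _course(xy: np.ndarray) -> np.ndarray:
    d = np.diff(xy, axis=0)
    ang = (np.degrees(np.arctan2(d[:, 0], d[:, 1]))) % 360.0  # clockwise from north
    return np.append(ang, ang[-1] if len(ang) else 0.0)


# ---------------------------------------------------------------------------
# per-trip builders


def _build_frame(
    xy: np.ndarray,
    t0: pd.Timestamp,
    seconds: np.ndarray,
    school: tuple[float, float],
    nickname: str,
    haccuracy: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    ll = _enu_to_latlon(xy, school)
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(seconds)
    dev_speed = np.append(step / np.maximum(dt, 1), 0.0)
    dev_speed = np.maximum(dev_speed + rng.normal(0.0, 0.1, len(dev_speed)), 0.0)
    return pd.DataFrame(
        {
            "course": _course(xy),
            "haccuracy": haccuracy,
            "latitude": ll[:, 0],
            "longitude": ll[:, 1],
            "speed": dev_speed,
            "time": t0 + pd.to_timedelta(seconds, unit="s"),
            "nickname": nickname,
        }
    )[RAW_COLUMNS]


def _burst_offsets(rng: np.random.Generator, k: int, lo: float, hi: float) -> np.ndarray:
    """k scattered offsets whose consecutive jumps (and the jump to the
    clean start) imply speeds in [lo, hi] m/s at 1 s spacing."""
    offs = np.zeros((k, 2))
    prev = np.zeros(2)
    for i in range(k):
        for _ in range(100):
            r = rng.uniform(15.0, min(hi * 0.55, 50.0))
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cand = np.array([r * np.cos(ang), r * np.sin(ang)])
            jump = np.linalg.norm(cand - prev)
            if lo <= jump <= hi:
                break
        offs[i] = cand
        prev = cand
    return offs


def _pedestrian_trip(
    rng: np.random.Generator, spec: CohortSpec, school: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, list[str], str, float]:
    """Build one pedestrian trip: (xy, seconds, labels, direction, mu)."""
    sigma_mu = np.sqrt(np.log1p((spec.speed_sd / spec.speed_mean) ** 2))
    mu = float(
        rng.lognormal(np.log(spec.speed_mean) - sigma_mu**2 / 2.0, sigma_mu)
    )
    duration = rng.uniform(spec.duration_min, spec.duration_max)
    # a slow short draw cannot reach the annulus; lengthen minimally
    L = max(mu * duration, spec.home_dist_min / 0.9)
    path = _grid_route(rng, L, spec.home_dist_min, spec.home_dist_max)

    xy = _walk_positions(rng, path, mu, spec.step_speed_cv)  # home -> school
    direction = (
        Direction.HOME_TO_SCHOOL if rng.random() < 0.5 else Direction.SCHOOL_TO_HOME
    )
    if direction is Direction.SCHOOL_TO_HOME:
        xy = xy[::-1].copy()
    xy = xy + _ar1_noise(rng, len(xy), spec.noise_sd, spec.noise_rho)

    labels_1hz = ["clean"] * len(xy)

    # terminal dwell cluster (GPS accumulating at the destination)
    if rng.random() < spec.p_dwell:
        m = int(rng.uniform(*spec.dwell_duration))
        jitter = _ar1_noise(rng, m, spec.dwell_jitter, 0.5)
        xy = np.vstack([xy, xy[-1] + jitter])
        labels_1hz += ["dwell"] * m

    # thin the whole 1 Hz record stream per the gap model
    if spec.gap_probs:
        keep = _sample_gaps(rng, spec, len(xy))
    else:
        keep = np.arange(len(xy))
    xy_s = xy[keep]
    seconds = keep.astype(int)
    labels = [labels_1hz[i] for i in keep]

    # startup outlier burst (GPS activation noise at the recording start)
    if rng.random() < spec.p_outlier_burst and spec.burst_max_records > 0:
        k = int(rng.integers(1, spec.burst_max_records + 1))
        offs = _burst_offsets(rng, k, *spec.burst_speed)[::-1]
        burst_xy = xy_s[0] + offs
        xy_s = np.vstack([burst_xy, xy_s])
        seconds = np.concatenate([np.arange(-k, 0), seconds])
        labels = ["outlier"] * k + labels

    return xy_s, seconds - seconds[0], labels, direction.value, mu


def _vehicle_trip(
    rng: np.random.Generator, spec: CohortSpec, school: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    speed = rng.uniform(6.0, 12.0)
    duration = rng.uniform(200.0, 500.0)
    L = speed * duration
    path = _grid_route(rng, L, 0.5 * L, 0.85 * L)
    xy = _walk_positions(rng, path, speed, 0.15)
    xy = xy + _ar1_noise(rng, len(xy), spec.noise_sd, spec.noise_rho)
    return xy, np.arange(len(xy))


def _scatter_trip(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = int(rng.integers(8, 46))
    r = rng.uniform(0.0, 80.0, n)
    ang = rng.uniform(0.0, 2.0 * np.pi, n)
    xy = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return xy, np.arange(n) * int(rng.integers(1, 4))


# ---------------------------------------------------------------------------
# cohort generation


_PED_MODE_TOKENS = ("WALK", "walk", "peu")
_VEHICLE_MODE_TOKENS = ("tren", "BUS", "metro", "car")
_COMP_TOKENS = ("ALONE", "alone", "acompanyat", None)


def generate_cohort(
    spec: CohortSpec | None = None,
    rng: np.random.Generator | None = None,
    out_dir=None,
) -> tuple[list[Trajectory], TruthLedger]:
    """Generate a labelled raw-dialect cohort.

    Returns the trajectories and the truth ledger; when ``out_dir`` is
    given the raw CSVs and ``truth_ledger.json`` are also written there.
    Identical seeds give byte-identical output.
    """
    spec = spec or CohortSpec()
    rng = rng or np.random.default_rng(spec.rng_seed)
    coords = dict(spec.school_coords) if spec.school_coords else load_school_coords()
    trajectories: list[Trajectory] = []
    ledger = TruthLedger()
    classes = [PEDESTRIAN, MODE_CONTAMINANT, UNLABELED_VEHICLE, SCATTER, NO_OD]
    pvals = np.array(
        [
            1.0
            - spec.frac_mode_contaminant
            - spec.frac_unlabeled_vehicle
            - spec.frac_scatter
            - spec.frac_no_od,
            spec.frac_mode_contaminant,
            spec.frac_unlabeled_vehicle,
            spec.frac_scatter,
            spec.frac_no_od,
        ]
    )
    base_date = pd.Timestamp(spec.start_date)
    for si, code in enumerate(spec.school_codes):
        school = coords[code]
        date = base_date + pd.Timedelta(days=si % 10)
        for pi in range(spec.n_participants):
            cls = classes[int(rng.choice(len(classes), p=pvals))]
            number = f"{pi + 1:04d}"
            comp = _COMP_TOKENS[int(rng.integers(len(_COMP_TOKENS)))]
            direction = None
            labels: list[str]
            mu = None
            if cls == MODE_CONTAMINANT:
                mode_tok = _VEHICLE_MODE_TOKENS[int(rng.integers(len(_VEHICLE_MODE_TOKENS)))]
                xy, seconds = _vehicle_trip(rng, spec, school)
                labels = ["clean"] * len(xy)
            elif cls == UNLABELED_VEHICLE:
                mode_tok = None
                xy, seconds = _vehicle_trip(rng, spec, school)
                labels = ["clean"] * len(xy)
            elif cls == SCATTER:
                mode_tok = "WALK" if rng.random() < 0.5 else None
                xy, seconds = _scatter_trip(rng)
                labels = ["clean"] * len(xy)
            elif cls == NO_OD:
                mode_tok = _PED_MODE_TOKENS[int(rng.integers(len(_PED_MODE_TOKENS)))]
                xy, seconds, labels, direction, mu = _pedestrian_trip(rng, spec, school)
                # shift the whole track so neither endpoint is near the school
                for _ in range(100):
                    ang = rng.uniform(0.0, 2.0 * np.pi)
                    shift = rng.uniform(500.0, 1000.0)
                    vec = np.array([shift * np.cos(ang), shift * np.sin(ang)])
                    ends = np.linalg.norm(xy[[0, -1]] + vec, axis=1)
                    if (ends > 2.0 * spec.school_radius).all():
                        break
                xy = xy + vec
            else:
                if rng.random() < spec.p_mode_missing:
                    mode_tok = None
                else:
                    mode_tok = _PED_MODE_TOKENS[int(rng.integers(len(_PED_MODE_TOKENS)))]
                xy, seconds, labels, direction, mu = _pedestrian_trip(rng, spec, school)

            parts = [code, number]
            if mode_tok:
                parts.append(mode_tok)
                if comp:
                    parts.append(comp)
            nickname = "_".join(parts)
            start = date + pd.Timedelta(hours=7, minutes=45, seconds=int(pi) * 90 + int(rng.integers(0, 60)))
            hacc = float(rng.choice([5.0, 10.0, 15.0, 25.0, 35.0]))
            df = _build_frame(xy, start, np.asarray(seconds), school, nickname, hacc, rng)
            parsed = parse_nickname(nickname)
            meta = TripMetadata(
                school_code=code,
                participant_number=number,
                trip_date=date,
                mode=parsed.mode,
                companionship=parsed.companionship,
            )
            traj = Trajectory(df=df, metadata=meta)
            traj.source_filename = trajectory_filename(traj, "raw")
            trajectories.append(traj)
            dts = np.diff(np.asarray(seconds))
            ledger.trajectories[traj.source_filename] = TrajTruth(
                key=traj.source_filename,
                school=code,
                cls=cls,
                direction=direction,
                mode_token=mode_tok,
                n_records=len(df),
                record_labels=list(labels),
                gap_extra_seconds=int((dts - 1).sum()),
                base_speed=mu,
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for traj in trajectories:
            write_trajectory(traj, out_dir / traj.source_filename, "raw")
        ledger.to_json(out_dir / "truth_ledger.json")
    return trajectories, ledger


# ---------------------------------------------------------------------------
# scoring the pipeline against the ledger


def _traj_stage_scores(
    report: StageReport, ledger: TruthLedger, target_classes: Sequence[str]
) -> dict:
    keys = [k for k in report.dispositions if k in ledger.trajectories]
    if len(keys) != len(report.dispositions):
        raise ValueError("ledger does not cover every trajectory in the report")
    removed = {k for k in keys if not report.dispositions[k].startswith("kept")}
    targets = {k for k in keys if ledger.trajectories[k].cls in target_classes}
    tp = len(removed & targets)
    recall = tp / len(targets) if targets else float("nan")
    precision = tp / len(removed) if removed else float("nan")
    return {
        "n_targets": len(targets),
        "n_removed": len(removed),
        "recall": recall,
        "precision": precision,
        "false_removals": sorted(removed - targets),
        "missed": sorted(targets - removed),
    }


def truth_eval(reports: Mapping[str, StageReport], ledger: TruthLedger) -> dict:
    """Per-stage confusion metrics of a pipeline run on a labelled cohort.

    ``reports`` maps stage name -> :class:`StageReport` (as produced by
    the stage transformers). Trajectory-level stages score removal
    against contaminant classes; the outlier stage scores removed
    *records* against the clean/outlier/dwell record labels.
    """
    out: dict = {}
    if "non_pedestrian" in reports:
        out["non_pedestrian"] = _traj_stage_scores(
            reports["non_pedestrian"], ledger, (MODE_CONTAMINANT, UNLABELED_VEHICLE)
        )
    if "origin_destination" in reports:
        out["origin_destination"] = _traj_stage_scores(
            reports["origin_destination"], ledger, (SCATTER, NO_OD)
        )
    if "outliers" in reports:
        rep = reports["outliers"]
        n_outlier = n_outlier_removed = 0
        n_clean = n_clean_removed = 0
        for key, disp in rep.dispositions.items():
            truth = ledger.trajectories.get(key)
            if truth is None:
                raise ValueError(f"trajectory {key} missing from ledger")
            lab = np.asarray(truth.record_labels)
            if disp.startswith("removed"):
                removed_idx = np.arange(len(lab))
            else:
                removed_idx = np.asarray(rep.removed_records.get(key, []), dtype=int)
            is_removed = np.zeros(len(lab), dtype=bool)
            is_removed[removed_idx] = True
            n_outlier += int((lab == "outlier").sum())
            n_outlier_removed += int(((lab == "outlier") & is_removed).sum())
            n_clean += int((lab == "clean").sum())
            n_clean_removed += int(((lab == "clean") & is_removed).sum())
        out["outliers"] = {
            "n_outlier_records": n_outlier,
            "outlier_recall": (n_outlier_removed / n_outlier) if n_outlier else float("nan"),
            "n_clean_records": n_clean,
            "clean_false_removal_rate": (n_clean_removed / n_clean) if n_clean else 0.0,
        }
    return out
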