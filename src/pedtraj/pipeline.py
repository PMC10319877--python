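"""End-to-end orchestration of the five processing stages.

Stage order is fixed: non-pedestrian removal -> origin-destination
validation -> outlier clean-up -> k-anonymity geomask -> 1 Hz linear
interpolation. Geomasking precedes interpolation so the resampled files
never contain masked-away time. Files that cannot be read or routed
through a stage are quarantined with a reason and the run continues — a
crowdsourced cohort is expected to contain malformed inputs.

Outputs mirror the published artifact layout: a ``processed_data``
folder of 10-column post-geomask files, an ``interpolated_data`` folder
of 1 Hz files, a JSON manifest with per-stage bookkeeping, and summary
tables (per-school movement statistics and the before/after geomask
record counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cleaning import (
    CleaningPolicy,
    NonPedestrianFilter,
    OriginDestinationValidator,
    OutlierRemover,
    StageReport,
    traj_key,
)
from .geomask import GeomaskStripper, load_school_coords
from .io import read_trajectory, trajectory_filename, write_trajectory
from .kinematics import attach_steps, cohort_table, summarize
from .records import Direction, Trajectory
from .resample import Interpolator1Hz, compare_pre_post_interpolation

logger = logging.getLogger(__name__)

ALL_STAGES = ("non_pedestrian", "origin_destination", "outliers", "geomask", "interpolate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    input_dir: str = "."
    output_dir: str = "out"
    school_coords_file: str | None = None  # default: packaged synthetic table
    districts_file: str | None = None
    cleaning: CleaningPolicy = field(default_factory=CleaningPolicy)
    t_min: int = 20
    t_max: int = 50
    v_assumed: float = 1.5
    direction_map: dict[str, str] = field(default_factory=dict)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cleaning = CleaningPolicy(**raw.pop("cleaning", {}))
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(cleaning=cleaning, **known)
        if "stages" in known:
            cfg.stages = tuple(known["stages"])
        return cfg


@dataclass
class PipelineResult:
    processed: list[Trajectory]
    interpolated: list[Trajectory]
    reports: dict[str, StageReport]
    manifest: dict
    quarantined: list[tuple[str, str]]  # (key, reason)


def read_cohort(input_dir) -> tuple[list[Trajectory], list[tuple[str, str]]]:
    """Read every raw-dialect CSV in a directory; unreadable files are
    quarantined (name, reason) instead of aborting the run."""
    trajs: list[Trajectory] = []
    quarantined: list[tuple[str, str]] = []
    for path in sorted(Path(input_dir).glob("*.csv")):
        if path.stem.endswith(("_processed", "_interpolated")):
            continue
        try:
            trajs.append(read_trajectory(path, "raw"))
        except Exception as exc:  # noqa: BLE001 - quarantine-not-abort policy
            logger.warning("quarantined %s: %s", path.name, exc)
            quarantined.append((path.name, str(exc)))
    return trajs, quarantined


def report_tables(
    pre_geomask: Sequence[Trajectory], post_geomask: Sequence[Trajectory]
) -> pd.DataFrame:
    """Per-school record counts and mean duration before/after the
    geomask, with a totals row (percentage reduction as integer %)."""
    def _by_school(trajs):
        out: dict[str, list[Trajectory]] = {}
        for t in trajs:
            out.setdefault(t.metadata.school_code or "?", []).append(t)
        return out

    pre_b, post_b = _by_school(pre_geomask), _by_school(post_geomask)
    rows = []
    for school in sorted(pre_b):
        pre, post = pre_b[school], post_b.get(school, [])
        g_pre = sum(len(t) for t in pre)
        g_post = sum(len(t) for t in post)
        rows.append(
            {
                "school": school,
                "participants": len(post),
                "gps_pre": g_pre,
                "gps_post": g_post,
                "reduction_pct": round(100.0 * (g_pre - g_post) / g_pre) if g_pre else 0,
                "T_mean_pre": np.mean([summarize(t).T for t in pre]) if pre else np.nan,
                "T_mean_post": np.mean([summarize(t).T for t in post]) if post else np.nan,
            }
        )
    g_pre = sum(r["gps_pre"] for r in rows)
    g_post = sum(r["gps_post"] for r in rows)
    rows.append(
        {
            "school": "Total",
            "participants": sum(r["participants"] for r in rows),
            "gps_pre": g_pre,
            "gps_post": g_post,
            "reduction_pct": round(100.0 * (g_pre - g_post) / g_pre) if g_pre else 0,
            "T_mean_pre": np.mean([summarize(t).T for t in pre_geomask])
            if pre_geomask
            else np.nan,
            "T_mean_post": np.mean([summarize(t).T for t in post_geomask])
            if post_geomask
            else np.nan,
        }
    )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    trajectories: Sequence[Trajectory] | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run the five stages over a cohort.

    ``trajectories`` bypasses reading ``config.input_dir`` (useful for
    in-memory cohorts). Identical config + seed gives identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    coords = load_school_coords(config.school_coords_file)
    if trajectories is None:
        cohort, quarantined = read_cohort(config.input_dir)
    else:
        cohort, quarantined = list(trajectories), []
    reports: dict[str, StageReport] = {}

    if "non_pedestrian" in config.stages:
        step = NonPedestrianFilter(v_nonped=config.cleaning.v_nonped).fit(cohort)
        cohort = step.transform(cohort)
        reports["non_pedestrian"] = step.report_

    if "origin_destination" in config.stages:
        routed = []
        for t in cohort:
            if t.metadata.school_matched and t.metadata.school_code not in coords:
                quarantined.append((traj_key(t), "no_school_coordinates"))
            else:
                routed.append(t)
        step = OriginDestinationValidator(
            school_coords=coords,
            school_radius=config.cleaning.school_radius,
            min_records=config.cleaning.min_records,
        ).fit(routed)
        cohort = step.transform(routed)
        reports["origin_destination"] = step.report_
        for t in step.review_:
            quarantined.append((traj_key(t), "unmatched_school_code"))

    if "outliers" in config.stages:
        step = OutlierRemover(
            v_outlier_max=config.cleaning.v_outlier_max,
            haccuracy_max=config.cleaning.haccuracy_max,
            max_outlier_fraction=config.cleaning.max_outlier_fraction,
            endpoint_dwell_radius=config.cleaning.endpoint_dwell_radius,
            endpoint_dwell_min=config.cleaning.endpoint_dwell_min,
        ).fit(cohort)
        cohort = step.transform(cohort)
        reports["outliers"] = step.report_

    pre_geomask = list(cohort)
    mask_report: dict = {}
    if "geomask" in config.stages:
        dmap = {k: Direction(v) for k, v in config.direction_map.items()}
        step = GeomaskStripper(
            t_min=config.t_min,
            t_max=config.t_max,
            v_assumed=config.v_assumed,
            min_remaining_records=config.cleaning.min_records,
            random_state=config.seed,
            school_coords=coords,
            direction_map=dmap or None,
        ).fit(cohort)
        cohort = step.transform(cohort)
        reports["geomask"] = step.report_
        mask_report = step.mask_report_

    processed = [attach_steps(t) for t in cohort]

    interpolated: list[Trajectory] = []
    if "interpolate" in config.stages:
        step = Interpolator1Hz().fit(processed)
        interpolated = step.transform(processed)
        reports["interpolate"] = step.report_

    manifest = {
        "seed": config.seed,
        "cleaning_policy": asdict(config.cleaning),
        "geomask": {"t_min": config.t_min, "t_max": config.t_max, "v": config.v_assumed},
        "stages": [r.to_dict() for r in reports.values()],
        "mask_report": mask_report,
        "quarantined": quarantined,
        "n_processed": len(processed),
        "n_interpolated": len(interpolated),
        "records_processed": int(sum(len(t) for t in processed)),
        "records_interpolated": int(sum(len(t) for t in interpolated)),
    }

    if write_outputs:
        out = Path(config.output_dir)
        (out / "processed_data").mkdir(parents=True, exist_ok=True)
        (out / "interpolated_data").mkdir(parents=True, exist_ok=True)
        for t in processed:
            write_trajectory(
                t, out / "processed_data" / trajectory_filename(t, "processed"),
                "processed",
            )
        for t in interpolated:
            write_trajectory(
                t, out / "interpolated_data" / trajectory_filename(t, "interpolated"),
                "interpolated",
            )
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str), encoding="utf-8"
        )
        if processed:
            cohort_table(processed).to_csv(out / "summary_processed.csv", index=False)
            report_tables(pre_geomask, processed).to_csv(
                out / "geomask_reduction.csv", index=False
            )
            if interpolated:
                cmp = compare_pre_post_interpolation(processed, interpolated)
                cmp["per_trajectory"].to_csv(
                    out / "pre_post_interpolation.csv", index=False
                )
    return PipelineResult(
        processed=processed,
        interpolated=interpolated,
        reports=reports,
        manifest=manifest,
        quarantined=quarantined,
    )
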