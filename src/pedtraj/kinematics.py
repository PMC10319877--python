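"""Step kinematics on the time-advanced convention.

For a trip with fixes at timestamps t_0 < t_1 < ... < t_{n-1}, the step
quantities at index i (i = 0 .. n-2) are

    dt_i = t_{i+1} - t_i            (s)
    d_i  = |r(t_{i+1}) - r(t_i)|    (m, great-circle)
    v_i  = d_i / dt_i               (m/s, instantaneous velocity)

and the trip summaries are the total path distance D = sum d_i, the
duration T = sum dt_i, the effective speed v_eff = D / T and the mean
instantaneous velocity v_m = mean(v_i). v(t) computed this way is
authoritative; the device-reported speed column is carried through the
files but never used.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import StepSeries, Trajectory, TrajectorySummary

logger = logging.getLogger(__name__)

#: mean Earth radius (m), IUGG value
EARTH_RADIUS_M = 6_371_008.8


def geodesic_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle (haversine) distance in meters between WGS84 points.

    Vectorised over array inputs. At the sub-10-km scale of a school
    commute the difference from an ellipsoidal geodesic is far below the
    ~0.1 m rounding of 6-decimal-place coordinates.
    """
    phi1 = np.radians(np.asarray(lat1, dtype=float))
    lam1 = np.radians(np.asarray(lon1, dtype=float))
    phi2 = np.radians(np.asarray(lat2, dtype=float))
    lam2 = np.radians(np.asarray(lon2, dtype=float))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def compute_steps(traj: Trajectory) -> StepSeries:
    """Compute the time-advanced step series of a trip.

    Step i uses fixes i and i+1; the returned arrays have length n-1 and
    the last fix carries no entry. A single-fix trip yields an empty
    series (with a warning) rather than an error.
    """
    ll = traj.latlon
    if len(ll) < 2:
        logger.warning("trajectory %s has < 2 records; empty step series", traj.nickname)
        empty = np.empty(0)
        return StepSeries(dt=empty, dist=empty.copy(), vel=empty.copy())
    t = traj.df["time"].to_numpy()
    dt = np.diff(t).astype("timedelta64[ns]").astype(float) / 1e9
    dist = geodesic_distance(ll[:-1, 0], ll[:-1, 1], ll[1:, 0], ll[1:, 1])
    return StepSeries(dt=dt, dist=np.atleast_1d(dist), vel=np.atleast_1d(dist) / dt)


def attach_steps(traj: Trajectory) -> Trajectory:
    """Return the same trajectory with a freshly computed step series."""
    traj.steps = compute_steps(traj)
    return traj


def summarize(traj: Trajectory, steps: StepSeries | None = None) -> TrajectorySummary:
    """Trip-level D, T, v_eff and v_m from the step series."""
    if steps is None:
        steps = traj.steps if traj.steps is not None else compute_steps(traj)
    T = float(steps.dt.sum())
    if T <= 0.0:
        raise ValueError(f"trajectory {traj.nickname}: zero duration (single instant)")
    D = float(steps.dist.sum())
    return TrajectorySummary(
        D=D, T=T, v_eff=D / T, v_m=float(steps.vel.mean()), n_records=len(traj)
    )


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def cohort_table(
    trajectories: Sequence[Trajectory],
    summaries: Sequence[TrajectorySummary] | None = None,
    group_by_school: bool = True,
) -> pd.DataFrame:
    """Per-school movement statistics table.

    One row per school (or a single ``all`` row): mean +/- standard error
    of D and T, their min/max over trips, mean +/- s.e. and min/max of the
    pooled instantaneous velocities, and cohort quartiles of T, D and
    v_eff. The +/- columns are standard errors of the mean. Empty groups
    are omitted.
    """
    if summaries is None:
        summaries = [summarize(t) for t in trajectories]
    rows = []
    keys = (
        sorted({t.metadata.school_code or "?" for t in trajectories})
        if group_by_school
        else ["all"]
    )
    for key in keys:
        idx = [
            i
            for i, t in enumerate(trajectories)
            if not group_by_school or (t.metadata.school_code or "?") == key
        ]
        if not idx:
            logger.info("cohort_table: empty group %s omitted", key)
            continue
        D = np.array([summaries[i].D for i in idx])
        T = np.array([summaries[i].T for i in idx])
        veff = np.array([summaries[i].v_eff for i in idx])
        vels = np.concatenate(
            [
                (trajectories[i].steps or compute_steps(trajectories[i])).vel
                for i in idx
            ]
        )
        rows.append(
            {
                "school": key,
                "n_trips": len(idx),
                "D_mean": D.mean(),
                "D_sem": _sem(D),
                "D_min": D.min(),
                "D_max": D.max(),
                "T_mean": T.mean(),
                "T_sem": _sem(T),
                "T_min": T.min(),
                "T_max": T.max(),
                "v_mean": vels.mean(),
                "v_sem": _sem(vels),
                "v_min": vels.min(),
                "v_max": vels.max(),
                "T_q1": np.quantile(T, 0.25),
                "T_q2": np.quantile(T, 0.50),
                "T_q3": np.quantile(T, 0.75),
                "D_q1": np.quantile(D, 0.25),
                "D_q2": np.quantile(D, 0.50),
                "D_q3": np.quantile(D, 0.75),
                "veff_mean": veff.mean(),
                "veff_sem": _sem(veff),
                "veff_q1": np.quantile(veff, 0.25),
                "veff_q2": np.quantile(veff, 0.50),
                "veff_q3": np.quantile(veff, 0.75),
            }
        )
    return pd.DataFrame(rows)
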