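"""Exposure-hour accounting of hourly house environment against age targets.

The pipeline here is: average duplicate sensors per house-hour, align each
flock's house records to hours of age from placement, quality-control each
aligned series, and count hours outside nested temperature bands, RH limits
and THI bounds for weekly and cumulative age windows.

Conventions
-----------
* Ages are 0-based; a flock spans hours of age 0..839 (35 days).
* Age windows are half-open in days: window (14, 21) covers hours of age
  [14*24, 21*24).  Performance "at 21 d" is conventionally paired with the
  window (14, 21).
* Exposure uses strict inequalities: an hour counts as below the band at
  depth ``d`` when ``t < t_rec - d``; a reading exactly on the boundary is
  in-band.
* Counts are over observed hours only; hours missing from an accepted series
  are excluded from both the counts and ``total_observed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import TargetSchedule, thi

__all__ = [
    "T_DELTAS",
    "WEEKLY_WINDOWS",
    "CUMULATIVE_WINDOWS",
    "BAND_COLUMNS",
    "band_label",
    "QCResult",
    "average_sensors",
    "align_age",
    "qc_flock",
    "compute_exposure",
    "flock_exposure",
]

#: Band depths in degC around the recommended temperature (nested).
T_DELTAS: tuple[float, ...] = (1.5, 2.5, 5.0, 7.0)

WEEKLY_WINDOWS: tuple[tuple[int, int], ...] = ((0, 7), (7, 14), (14, 21), (21, 28), (28, 35))
CUMULATIVE_WINDOWS: tuple[tuple[int, int], ...] = ((0, 7), (0, 14), (0, 21), (0, 28), (0, 35))

HOURS_PER_DAY = 24
CYCLE_HOURS = 840  # 35 d


def band_label(kind: str, delta: float | None = None) -> str:
    """Column name for one exposure band, e.g. ``t_below_2.5`` or ``thi_above``."""
    if kind in ("t_below", "t_above"):
        return f"{kind}_{delta:g}"
    return kind


#: All exposure-count columns, in fixed output order.
BAND_COLUMNS: tuple[str, ...] = tuple(
    [band_label("t_below", d) for d in T_DELTAS]
    + [band_label("t_above", d) for d in T_DELTAS]
    + ["rh_below_50", "rh_above_75", "rh_out", "thi_below", "thi_above"]
)


def average_sensors(env: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate sensor readings per (farm, house, timestamp).

    Returns one row per house-hour with mean ``t`` and ``rh`` and the number
    of sensors that contributed (``n_sensors``).  Hours with a single sensor
    simply pass that sensor through.
    """
    required = {"farm_id", "house_id", "timestamp", "t", "rh"}
    missing = required - set(env.columns)
    if missing:
        raise ValueError(f"environment table is missing columns: {sorted(missing)}")
    out = (
        env.groupby(["farm_id", "house_id", "timestamp"], as_index=False, sort=True)
        .agg(t=("t", "mean"), rh=("rh", "mean"), n_sensors=("t", "size"))
    )
    return out


def align_age(house_hours: pd.DataFrame, placement: pd.Timestamp) -> pd.DataFrame:
    """Convert one house's hourly records to hours of age from ``placement``.

    Keeps hours of age in [0, 840) (half-open window: the hour starting
    839 h after placement is the last one retained).  Returns a frame with
    ``hour_of_age``, ``age_day``, ``t``, ``rh`` sorted by age.
    """
    placement = pd.Timestamp(placement)
    delta = house_hours["timestamp"] - placement
    hour_of_age = np.floor(delta / pd.Timedelta(hours=1)).astype(int)
    keep = (hour_of_age >= 0) & (hour_of_age < CYCLE_HOURS)
    out = house_hours.loc[keep, ["t", "rh"]].copy()
    out.insert(0, "hour_of_age", hour_of_age[keep].to_numpy())
    out.insert(1, "age_day", out["hour_of_age"].to_numpy() // HOURS_PER_DAY)
    out = out.sort_values("hour_of_age").reset_index(drop=True)
    if out["hour_of_age"].duplicated().any():
        raise ValueError("duplicate hour_of_age after alignment; average sensors first")
    return out


@dataclass
class QCResult:
    """Keep/drop decision for one aligned flock series."""

    flock_id: str
    keep: bool
    n_hours: int
    reasons: list[str] = field(default_factory=list)


def qc_flock(
    series: pd.DataFrame,
    flock_id: str = "",
    *,
    completeness_min: float = 0.995,
    t_physical: tuple[float, float] = (-5.0, 45.0),
    expected_hours: int = CYCLE_HOURS,
) -> QCResult:
    """Quality-control one aligned series.

    Drops the flock when fewer than ``completeness_min * expected_hours``
    hours were observed, or when any temperature falls outside the
    physically plausible range ``t_physical``, or any RH outside [0, 100].
    """
    reasons = []
    n = len(series)
    if n < completeness_min * expected_hours:
        reasons.append(f"incomplete: {n}/{expected_hours} hours observed")
    lo, hi = t_physical
    t = series["t"].to_numpy()
    rh = series["rh"].to_numpy()
    if np.any((t < lo) | (t > hi)) or np.any(~np.isfinite(t)):
        reasons.append(f"physical outlier: temperature outside [{lo}, {hi}] degC")
    if np.any((rh < 0) | (rh > 100)) or np.any(~np.isfinite(rh)):
        reasons.append("physical outlier: RH outside [0, 100] %")
    return QCResult(flock_id=flock_id, keep=not reasons, n_hours=n, reasons=reasons)


def _default_windows() -> list[tuple[str, int, int]]:
    wins = [("week", s, e) for s, e in WEEKLY_WINDOWS]
    wins += [("cum", s, e) for s, e in CUMULATIVE_WINDOWS]
    return wins


def compute_exposure(
    series: pd.DataFrame,
    schedule: TargetSchedule,
    flock_id: str = "",
    windows: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Count exposure hours outside each environmental band per age window.

    ``series`` is an aligned (and QC-accepted) per-flock frame with
    ``hour_of_age``, ``age_day``, ``t``, ``rh``.  Returns one row per window
    with one column per band (see :data:`BAND_COLUMNS`), plus
    ``total_observed``.
    """
    if windows is None:
        windows = _default_windows()
    ages = series["age_day"].to_numpy()
    if ages.size and ages.max() > schedule.max_age_day:
        raise ValueError("series contains ages beyond the schedule coverage")
    sched = schedule.lookup(ages)
    t = series["t"].to_numpy()
    rh = series["rh"].to_numpy()
    t_rec = sched["t_rec"].to_numpy()
    dev = t - t_rec
    rh_clipped = np.clip(rh, 0.0, 100.0)
    thi_val = thi(t, rh_clipped)
    thi_lo = sched["thi_low"].to_numpy()
    thi_hi = sched["thi_high"].to_numpy()
    rh_lo = sched["rh_low"].to_numpy()
    rh_hi = sched["rh_high"].to_numpy()
    hour = series["hour_of_age"].to_numpy()

    flags = {}
    for d in T_DELTAS:
        flags[band_label("t_below", d)] = dev < -d
        flags[band_label("t_above", d)] = dev > d
    flags["rh_below_50"] = rh < rh_lo
    flags["rh_above_75"] = rh > rh_hi
    flags["rh_out"] = flags["rh_below_50"] | flags["rh_above_75"]
    flags["thi_below"] = thi_val < thi_lo
    flags["thi_above"] = thi_val > thi_hi

    rows = []
    for kind, start_day, end_day in windows:
        mask = (hour >= start_day * HOURS_PER_DAY) & (hour < end_day * HOURS_PER_DAY)
        row = {
            "flock_id": flock_id,
            "kind": kind,
            "start_day": start_day,
            "end_day": end_day,
        }
        for col in BAND_COLUMNS:
            row[col] = int(np.count_nonzero(flags[col] & mask))
        row["total_observed"] = int(np.count_nonzero(mask))
        rows.append(row)
    return pd.DataFrame(rows)


def flock_exposure(
    env: pd.DataFrame,
    flocks: pd.DataFrame,
    schedule: TargetSchedule,
    *,
    completeness_min: float = 0.995,
    t_physical: tuple[float, float] = (-5.0, 45.0),
    windows: list[tuple[str, int, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full exposure pipeline: average, align, QC, count, for every flock.

    ``flocks`` needs columns ``flock_id``, ``house_id``, ``placement``.
    Returns ``(exposure, qc_report)``: exposure rows only for flocks that
    passed QC; the QC report has one row per flock with keep flag and
    reasons.  Flocks whose house has no overlapping records are dropped with
    reason ``no overlap``.
    """
    hourly = average_sensors(env)
    by_house = dict(tuple(hourly.groupby("house_id", sort=False)))
    exp_frames = []
    qc_rows = []
    for row in flocks.itertuples(index=False):
        house = by_house.get(row.house_id)
        if house is None or house.empty:
            qc_rows.append(
                {"flock_id": row.flock_id, "keep": False, "n_hours": 0,
                 "reasons": "no overlap: house has no records"}
            )
            continue
        series = align_age(house, row.placement)
        if series.empty:
            qc_rows.append(
                {"flock_id": row.flock_id, "keep": False, "n_hours": 0,
                 "reasons": "no overlap: no hours within the growing cycle"}
            )
            continue
        qc = qc_flock(
            series,
            row.flock_id,
            completeness_min=completeness_min,
            t_physical=t_physical,
        )
        qc_rows.append(
            {"flock_id": qc.flock_id, "keep": qc.keep, "n_hours": qc.n_hours,
             "reasons": "; ".join(qc.reasons)}
        )
        if qc.keep:
            exp_frames.append(compute_exposure(series, schedule, row.flock_id, windows))
    exposure = (
        pd.concat(exp_frames, ignore_index=True)
        if exp_frames
        else pd.DataFrame(columns=["flock_id", "kind", "start_day", "end_day",
                                   *BAND_COLUMNS, "total_observed"])
    )
    qc_report = pd.DataFrame(qc_rows)
    return exposure, qc_report
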