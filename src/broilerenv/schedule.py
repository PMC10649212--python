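"""Age-specific environmental targets for broiler houses.

A brooding schedule gives, for every day of age, the recommended mean house
temperature, an ideal band around it, relative-humidity limits, and derived
bounds on a thermal-humidity index (THI).  The THI used here is bilinear in
temperature and relative humidity,

    THI = 3.43 + 1.058*T - 0.293*RH + 0.0164*T*RH + 35.7

with T in degrees Celsius and RH in percent.  Because the index is bilinear,
its extrema over a rectangle of (T, RH) values are attained at the four
corners, which is how the per-day THI bounds are derived from the
temperature band and the RH limits.

The recommended temperature declines with age (chicks need supplemental heat
early in life); schedules are validated to be non-increasing in age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThiCoefficients",
    "DEFAULT_THI_COEFFICIENTS",
    "DEFAULT_ANCHORS",
    "TargetScheduleEntry",
    "TargetSchedule",
    "thi",
    "thi_bounds",
    "build_schedule",
]


@dataclass(frozen=True)
class ThiCoefficients:
    """Coefficients of the bilinear thermal-humidity index.

    Defaults are the published values used throughout this package.  The two
    additive constants (``const`` and ``offset``) are kept separate because
    that is how the source equation is printed; only their sum matters
    numerically.
    """

    const: float = 3.43
    per_t: float = 1.058
    per_rh: float = -0.293
    per_t_rh: float = 0.0164
    offset: float = 35.7

    def validate(self) -> None:
        for name in ("const", "per_t", "per_rh", "per_t_rh", "offset"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"THI coefficient {name!r} must be finite, got {v!r}")


DEFAULT_THI_COEFFICIENTS = ThiCoefficients()

#: Default brooding curve anchors: (age_day, recommended T in degC).  30 degC at
#: placement cooling linearly to 21 degC at day 27, constant thereafter.
DEFAULT_ANCHORS: tuple[tuple[int, float], ...] = ((0, 30.0), (27, 21.0))


def thi(t, rh, coef: ThiCoefficients | None = None):
    """Thermal-humidity index of temperature ``t`` (degC) and ``rh`` (%).

    Vectorised over numpy arrays.  ``rh`` must lie in [0, 100].
    """
    coef = coef or DEFAULT_THI_COEFFICIENTS
    t_arr = np.asarray(t, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise ValueError("relative humidity must be within [0, 100] %")
    out = (
        coef.const
        + coef.per_t * t_arr
        + coef.per_rh * rh_arr
        + coef.per_t_rh * t_arr * rh_arr
        + coef.offset
    )
    if np.isscalar(t) and np.isscalar(rh):
        return float(out)
    return out


def thi_bounds(
    t_rec: float,
    t_halfwidth: float,
    rh_low: float,
    rh_high: float,
    coef: ThiCoefficients | None = None,
) -> tuple[float, float]:
    """Min/max THI over the rectangle [t_rec +/- halfwidth] x [rh_low, rh_high].

    The index is bilinear, so the extrema over the rectangle are attained at
    its four corners; evaluating the corners is exact.
    """
    corners = [
        thi(t_rec - t_halfwidth, rh_low, coef),
        thi(t_rec - t_halfwidth, rh_high, coef),
        thi(t_rec + t_halfwidth, rh_low, coef),
        thi(t_rec + t_halfwidth, rh_high, coef),
    ]
    return (min(corners), max(corners))


@dataclass(frozen=True)
class TargetScheduleEntry:
    """Recommended environment for one day of age."""

    age_day: int
    t_rec: float
    t_halfwidth: float = 1.5
    rh_low: float = 50.0
    rh_high: float = 75.0
    thi_low: float = float("nan")
    thi_high: float = float("nan")

    def validate(self) -> None:
        if self.t_halfwidth <= 0:
            raise ValueError("t_halfwidth must be positive")
        if not (0 <= self.rh_low < self.rh_high <= 100):
            raise ValueError("require 0 <= rh_low < rh_high <= 100")
        if self.thi_low > self.thi_high:
            raise ValueError("thi_low must not exceed thi_high")


class TargetSchedule:
    """Per-day recommended environment for ages 0..max_age_day.

    Access the underlying table through :attr:`frame` (indexed by
    ``age_day``) or per-day entries through :attr:`entries`.
    """

    COLUMNS = ("t_rec", "t_halfwidth", "rh_low", "rh_high", "thi_low", "thi_high")

    def __init__(self, entries: Sequence[TargetScheduleEntry]):
        if not entries:
            raise ValueError("schedule must contain at least one entry")
        for e in entries:
            e.validate()
        ages = [e.age_day for e in entries]
        if ages != sorted(set(ages)):
            raise ValueError("schedule entries must have unique, sorted ages")
        t = [e.t_rec for e in entries]
        if any(b > a + 1e-12 for a, b in zip(t, t[1:])):
            raise ValueError("recommended temperature must be non-increasing with age")
        self.entries: tuple[TargetScheduleEntry, ...] = tuple(entries)
        self.frame = pd.DataFrame(
            {c: [getattr(e, c) for e in entries] for c in self.COLUMNS},
            index=pd.Index(ages, name="age_day"),
        )

    @property
    def max_age_day(self) -> int:
        return int(self.frame.index.max())

    def lookup(self, age_day) -> pd.DataFrame:
        """Rows of the schedule for an array of ages (raises if any missing)."""
        age_day = np.asarray(age_day)
        try:
            return self.frame.loc[age_day]
        except KeyError as exc:
            raise ValueError(f"schedule does not cover requested ages: {exc}") from exc

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TargetSchedule":
        frame = pd.read_csv(path).set_index("age_day")
        entries = [
            TargetScheduleEntry(age_day=int(age), **row[list(cls.COLUMNS)].to_dict())
            for age, row in frame.iterrows()
        ]
        return cls(entries)


def build_schedule(
    anchors: Iterable[tuple[int, float]] = DEFAULT_ANCHORS,
    *,
    max_age_day: int = 35,
    t_halfwidth: float = 1.5,
    rh_low: float = 50.0,
    rh_high: float = 75.0,
    coef: ThiCoefficients | None = None,
) -> TargetSchedule:
    """Build a per-day schedule by linear interpolation between anchor ages.

    ``anchors`` are (age_day, recommended T) pairs; at least two are needed
    and the first must be day 0.  Beyond the last anchor the recommendation
    is held constant.  THI bounds are filled from the temperature band and
    RH limits via :func:`thi_bounds`.
    """
    coef = coef or DEFAULT_THI_COEFFICIENTS
    coef.validate()
    anchor_list = sorted((int(d), float(t)) for d, t in anchors)
    if len(anchor_list) < 2:
        raise ValueError("need at least two anchor ages to build a schedule")
    if anchor_list[0][0] != 0:
        raise ValueError("schedule anchors must start at day 0")
    if t_halfwidth <= 0:
        raise ValueError("t_halfwidth must be positive")
    days = np.arange(max_age_day + 1)
    xp = [d for d, _ in anchor_list]
    fp = [t for _, t in anchor_list]
    t_rec = np.interp(days, xp, fp)
    entries = []
    for day, t in zip(days, t_rec):
        lo, hi = thi_bounds(float(t), t_halfwidth, rh_low, rh_high, coef)
        entries.append(
            TargetScheduleEntry(
                age_day=int(day),
                t_rec=float(t),
                t_halfwidth=t_halfwidth,
                rh_low=rh_low,
                rh_high=rh_high,
                thi_low=lo,
                thi_high=hi,
            )
        )
    return TargetSchedule(entries)
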