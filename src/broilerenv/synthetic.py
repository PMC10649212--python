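"""Synthetic broiler-flock data with the structure the analysis assumes.

Real commercial sensor and performance records of this kind are proprietary,
so every downstream stage of the package is exercised against a generator
that emulates them:

* hourly house temperature/RH series with a tropical diurnal cycle, two
  noisy sensors per house, optional cold-night depression, and optional
  controlled "excursions" (sustained deviations pinned at a fixed offset
  from the age target, emulating heating/ventilation failures);
* farm survey attributes drawn from region-stratified distributions
  (technification level, hatchery, litter, altitude, transport distance,
  downtime, house-infrastructure fractions);
* weekly flock performance (BW, BW gain, FCR, weekly and cumulative
  mortality) driven by additive linear exposure-response models: for each
  configured (response, window, band) the generator adds
  ``slope * exposure_hours`` to the response, where the exposure hours are
  computed from the generated environment by the same exposure engine the
  analysis uses.  Gaussian noise plus sex and farm offsets complete the
  model, so the configured slopes are exactly recoverable by ordinary least
  squares in the noise-free limit.

Determinism: the same :class:`GeneratorConfig` (including ``seed``) yields
bit-identical output.  Randomness is split over independent seed-sequence
children per flock so that, e.g., flock 7's environment does not depend on
how many sensors flock 3 has.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import (
    CYCLE_HOURS,
    HOURS_PER_DAY,
    average_sensors,
    align_age,
    compute_exposure,
)
from .schedule import DEFAULT_ANCHORS, TargetSchedule, build_schedule

__all__ = [
    "Excursion",
    "ExposureEffect",
    "GeneratorConfig",
    "SyntheticDataset",
    "DEFAULT_EXPOSURE_EFFECTS",
    "gen_env_series",
    "gen_farm_attributes",
    "gen_flocks",
    "gen_performance",
    "inject_faults",
    "generate",
]

REGIONS = ("Northwest", "Midwest", "East")
PERF_AGES = (7, 14, 21, 28, 35)
NIGHT_HOURS = frozenset({22, 23, 0, 1, 2, 3, 4, 5})
AFTERNOON_HOURS = frozenset({11, 12, 13, 14, 15, 16})


@dataclass(frozen=True)
class Excursion:
    """A controlled environmental deviation applied to a fraction of flocks.

    During randomly chosen eligible hours within the age window
    [start_day, end_day), house temperature is pinned at
    ``t_rec(age) + dt`` (degC) and, if ``rh`` is given, RH is pinned at that
    value.  Cold excursions (dt <= 0) are placed at night hours, warm ones in
    the afternoon.  The per-flock number of excursion hours is drawn
    uniformly from [hours_min, hours_max], giving a spread of exposure hours
    across flocks.
    """

    start_day: int
    end_day: int
    dt: float
    hours_min: int
    hours_max: int
    rh: float | None = None
    fraction: float = 1.0


@dataclass(frozen=True)
class ExposureEffect:
    """One linear exposure-response term: response += slope * hours.

    ``band`` is an exposure column name (e.g. ``t_below_5``, ``thi_below``),
    ``kind`` is ``week`` or ``cum`` and (start_day, end_day) the age window
    of the exposure.  ``response`` is one of ``bw``, ``fcr``,
    ``week_mortality``, ``cum_mortality``; ``age_day`` the age the response
    is read at.  Cumulative-mortality effects are applied to the weekly
    mortality of the week ending at ``age_day`` so that cumulative mortality
    at that age and every later age carries the term exactly once.
    """

    response: str
    age_day: int
    band: str
    kind: str
    start_day: int
    end_day: int
    slope: float


#: Default generative truth: the exposure-response slopes the package's
#: regression stage is expected to recover.  Units: response units per hour
#: of exposure.
DEFAULT_EXPOSURE_EFFECTS: tuple[ExposureEffect, ...] = (
    # Cold (5 degC below target) depresses BW in the same-age week.
    ExposureEffect("bw", 7, "t_below_5", "week", 0, 7, -1.51),
    ExposureEffect("bw", 14, "t_below_5", "week", 7, 14, -3.50),
    ExposureEffect("bw", 21, "t_below_5", "week", 14, 21, -4.91),
    # Mild cold (2.5 degC below) worsens FCR.
    ExposureEffect("fcr", 14, "t_below_2.5", "week", 7, 14, 0.011),
    ExposureEffect("fcr", 21, "t_below_2.5", "week", 14, 21, 0.004),
    ExposureEffect("fcr", 35, "t_below_2.5", "cum", 0, 28, 0.004),
    # Hours below the recommended THI bound worsen FCR at 21 d.
    ExposureEffect("fcr", 21, "thi_below", "week", 14, 21, 0.007),
    # Heat (7 degC above target) during 7-14 d raises last-week mortality.
    ExposureEffect("week_mortality", 35, "t_above_7", "week", 7, 14, 0.028),
    # Cumulative mild cold over 0-28 d raises mortality at 28 d (and hence
    # cumulative mortality at 28 and 35 d) by 0.018 % per hour.
    ExposureEffect("cum_mortality", 28, "t_below_2.5", "cum", 0, 28, 0.018),
    # Low-RH effects (weekly windows, small slopes).
    ExposureEffect("fcr", 7, "rh_below_50", "week", 0, 7, -0.002),
    ExposureEffect("week_mortality", 21, "rh_below_50", "week", 14, 21, -0.004),
    ExposureEffect("fcr", 28, "rh_below_50", "week", 21, 28, 0.003),
    ExposureEffect("fcr", 28, "rh_above_75", "cum", 0, 28, 0.0002),
)

# Region-stratified survey distributions.  Categorical tables are
# probabilities; continuous tables are (mean, sd, min, max) with draws
# truncated to [min, max].
DEFAULT_SURVEY: dict = {
    "region_probs": {"Northwest": 42 / 86, "Midwest": 17 / 86, "East": 27 / 86},
    "p_high_tech": {"Northwest": 7 / 42, "Midwest": 9 / 17, "East": 10 / 27},
    "hatchery": {"Northwest": "Hatchery 1", "Midwest": "Hatchery 2", "East": "Hatchery 2"},
    "p_rice_hulls": {"Northwest": 0.0, "Midwest": 1 / 17, "East": 1.0},
    "altitude": {
        "Northwest": (1588, 398, 1050, 2353),
        "Midwest": (1184, 300, 915, 1955),
        "East": (1184, 466, 99, 2253),
    },
    "litter_reuse": {
        "Northwest": (1.9, 1.85, 0, 12),
        "Midwest": (5.58, 4.15, 0, 12),
        "East": (0.44, 0.57, 0, 2),
    },
    "distance_km": {
        "Northwest": (39.1, 18.6, 5, 80),
        "Midwest": (188.8, 29.4, 132, 245),
        "East": (444.6, 40, 358, 531),
    },
    "distance_h": {
        "Northwest": (1.5, 0.6, 0.1, 3),
        "Midwest": (5.4, 0.7, 4, 6.5),
        "East": (8.3, 1.1, 6, 11),
    },
    "downtime_d": {
        "Northwest": (14.1, 0.4, 14, 16),
        "Midwest": (16.3, 1.4, 14, 21),
        "East": (13.0, 1.6, 11, 20),
    },
    "farm_area_m2": {
        "Northwest": (6435, 4607, 1620, 24992),
        "Midwest": (12655, 8761, 1440, 31680),
        "East": (7795, 9238, 1240, 48956),
    },
    # House-infrastructure category probabilities per region (normalised
    # from region house counts).
    "house_type": {
        "Northwest": {"open_sided": 358, "retrofitted": 15, "controlled": 0},
        "Midwest": {"open_sided": 118, "retrofitted": 21, "controlled": 12},
        "East": {"open_sided": 194, "retrofitted": 23, "controlled": 0},
    },
    "floor": {
        "Northwest": {"soil": 273, "concrete": 90},
        "Midwest": {"soil": 61, "concrete": 92},
        "East": {"soil": 96, "concrete": 121},
    },
    "water": {
        "Northwest": {"covered": 202, "uncovered": 157, "underground": 2},
        "Midwest": {"covered": 118, "uncovered": 41, "underground": 0},
        "East": {"covered": 148, "uncovered": 69, "underground": 0},
    },
    "p_two_stories": {"Northwest": 101 / 363, "Midwest": 10 / 153, "East": 0.0},
}


def _default_noise() -> dict:
    return {"bw": 15.0, "fcr": 0.02, "week_mortality": 0.05}


def _default_farm_sd() -> dict:
    return {"bw": 15.0, "fcr": 0.01, "week_mortality": 0.03}


def _default_sex_bw() -> dict:
    # Additive male/female half-gap per age (males + offset, females -).
    return {7: 6.0, 14: 16.0, 21: 35.0, 28: 62.0, 35: 90.0}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    Defaults are the study conditions: 80 flocks over 29 farms, 35-d cycles
    (840 hourly records per flock), two sensors per house, tropical diurnal
    cycling with cold-night depression on half the flocks, survey attribute
    distributions stratified by region, and exposure-response truth given by
    :data:`DEFAULT_EXPOSURE_EFFECTS`.
    """

    n_farms: int = 29
    n_flocks: int = 80
    seed: int = 0
    # Environment model
    schedule_anchors: tuple = DEFAULT_ANCHORS
    region_t_offset: dict = field(default_factory=lambda: dict.fromkeys(REGIONS, 0.0))
    diurnal_amplitude: float = 2.0
    diurnal_peak_hour: int = 15
    env_noise_sd: float = 0.5
    rh_mean: float = 65.0
    rh_amplitude: float = 12.0
    rh_noise_sd: float = 3.0
    rh_clip: tuple[float, float] = (30.32, 92.0)
    n_sensors: int = 2
    sensor_noise_sd: float = 0.3
    cold_night_fraction: float = 0.5
    cold_night_depression: float = 4.0
    excursions: tuple[Excursion, ...] = ()
    # Performance model
    exposure_effects: tuple[ExposureEffect, ...] = DEFAULT_EXPOSURE_EFFECTS
    response_noise_sd: dict = field(default_factory=_default_noise)
    farm_offset_sd: dict = field(default_factory=_default_farm_sd)
    bw_base: dict = field(default_factory=lambda: {7: 170.0, 14: 440.0, 21: 900.0, 28: 1430.0, 35: 1880.0})
    chick_weight: float = 40.0
    fcr_base: dict = field(default_factory=lambda: {7: 0.85, 14: 1.05, 21: 1.284, 28: 1.38, 35: 1.49})
    week_mortality_base: dict = field(default_factory=lambda: {7: 0.35, 14: 0.30, 21: 0.25, 28: 0.25, 35: 0.208})
    sex_bw_offset: dict = field(default_factory=_default_sex_bw)
    sex_fcr_offset: float = 0.015  # females + offset, males -
    female_fraction: float = 42 / 80
    # Survey + faults
    survey: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_SURVEY))
    fault_rate: float = 0.05
    placement_start: str = "2020-01-06 08:00"

    def validate(self) -> None:
        if self.n_flocks < 1 or self.n_farms < 1:
            raise ValueError("n_flocks and n_farms must be positive")
        for name in ("diurnal_amplitude", "env_noise_sd", "rh_noise_sd",
                     "sensor_noise_sd", "rh_amplitude", "cold_night_depression"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.fault_rate <= 1.0):
            raise ValueError("fault_rate must be within [0, 1]")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be within [0, 1]")
        if any(sd < 0 for sd in self.response_noise_sd.values()):
            raise ValueError("response noise SDs must be non-negative")
        probs = self.survey["region_probs"]
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("region_probs must sum to 1")
        for exc in self.excursions:
            if exc.end_day * HOURS_PER_DAY > CYCLE_HOURS:
                raise ValueError("excursion window extends beyond the 35-d cycle")
            if not (0.0 <= exc.fraction <= 1.0):
                raise ValueError("excursion fraction must be within [0, 1]")
        for eff in self.exposure_effects:
            if eff.end_day > 35:
                raise ValueError("exposure effect window references ages > 35 d")
            if eff.age_day not in PERF_AGES:
                raise ValueError(f"effect response age must be one of {PERF_AGES}")

    def schedule(self) -> TargetSchedule:
        return build_schedule(self.schedule_anchors)


@dataclass
class SyntheticDataset:
    """One generated study: environment, flocks, farms, performance, truth."""

    env: pd.DataFrame
    flocks: pd.DataFrame
    farms: pd.DataFrame
    performance: pd.DataFrame
    truth: pd.DataFrame
    fault_manifest: pd.DataFrame
    config: GeneratorConfig

    def to_csv(self, outdir) -> dict[str, str]:
        """Write the dataset as plain CSV files; returns {name: path}."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, frame in [
            ("env", self.env), ("flocks", self.flocks), ("farms", self.farms),
            ("performance", self.performance), ("truth", self.truth),
            ("fault_manifest", self.fault_manifest),
        ]:
            p = os.path.join(outdir, f"{name}.csv")
            frame.to_csv(p, index=False)
            paths[name] = p
        return paths


def _seed_layout(config: GeneratorConfig):
    root = np.random.SeedSequence(config.seed)
    k_farm, k_flock, k_env, k_perf, k_fault = root.spawn(5)
    return {
        "farm": np.random.default_rng(k_farm),
        "flock": np.random.default_rng(k_flock),
        "env": k_env.spawn(config.n_flocks),
        "perf": k_perf.spawn(config.n_flocks + 1),
        "fault": np.random.default_rng(k_fault),
    }


def _trunc_normal(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_farm_attributes(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one row of survey attributes per farm (region-stratified)."""
    config.validate()
    if rng is None:
        rng = _seed_layout(config)["farm"]
    sv = config.survey
    n = config.n_farms
    regions = rng.choice(list(sv["region_probs"]), size=n, p=list(sv["region_probs"].values()))
    rows = []
    for i, region in enumerate(regions):
        high = rng.random() < sv["p_high_tech"][region]
        litter = "rice hulls" if rng.random() < sv["p_rice_hulls"][region] else "wood shavings"
        cont = {
            key: float(_trunc_normal(rng, *sv[key][region], size=1)[0])
            for key in ("altitude", "litter_reuse", "distance_km", "distance_h",
                        "downtime_d", "farm_area_m2")
        }
        n_houses = int(rng.integers(1, 11))
        house_p = _norm_probs(sv["house_type"][region])
        house_counts = rng.multinomial(n_houses, list(house_p.values()))
        floor_p = _norm_probs(sv["floor"][region])
        concrete = rng.binomial(n_houses, floor_p["concrete"]) / n_houses
        water_p = _norm_probs(sv["water"][region])
        water_counts = rng.multinomial(n_houses, list(water_p.values()))
        rows.append({
            "farm_id": f"F{i:03d}",
            "region": region,
            "technification": "high" if high else "low",
            "hatchery": sv["hatchery"][region],
            "litter_type": litter,
            "altitude": cont["altitude"],
            "litter_reuse_cycles": round(cont["litter_reuse"], 1),
            "distance_km": cont["distance_km"],
            "distance_h": cont["distance_h"],
            "downtime_d": cont["downtime_d"],
            "farm_area_m2": cont["farm_area_m2"],
            "n_houses": n_houses,
            "pct_open_sided": house_counts[0] / n_houses,
            "pct_retrofitted": house_counts[1] / n_houses,
            "pct_controlled": house_counts[2] / n_houses,
            "pct_concrete_floor": concrete,
            "pct_water_covered": water_counts[0] / n_houses,
            "pct_water_uncovered": water_counts[1] / n_houses,
            "pct_water_underground": water_counts[2] / n_houses,
            "stories": 2 if rng.random() < sv["p_two_stories"][region] else 1,
        })
    return pd.DataFrame(rows)


def _norm_probs(counts: dict) -> dict:
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("category counts must sum to a positive total")
    return {k: v / total for k, v in counts.items()}


def gen_flocks(config: GeneratorConfig, farms: pd.DataFrame,
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign flocks to farms/houses, draw sex, stagger placements."""
    if rng is None:
        rng = _seed_layout(config)["flock"]
    start = pd.Timestamp(config.placement_start)
    rows = []
    for i in range(config.n_flocks):
        farm = farms.iloc[i % len(farms)]
        sex = "female" if rng.random() < config.female_fraction else "male"
        rows.append({
            "flock_id": f"FL{i:03d}",
            "farm_id": farm["farm_id"],
            "house_id": f"{farm['farm_id']}-H{i:03d}",
            "sex": sex,
            "region": farm["region"],
            "placement": start + pd.Timedelta(days=int(i % 28)),
        })
    return pd.DataFrame(rows)


def _truth_series(config: GeneratorConfig, flock, schedule: TargetSchedule,
                  rng: np.random.Generator) -> pd.DataFrame:
    """One flock's hourly true (pre-sensor-noise) T/RH over 840 h."""
    hours = np.arange(CYCLE_HOURS)
    age_day = hours // HOURS_PER_DAY
    timestamps = flock.placement + pd.to_timedelta(hours, unit="h")
    hod = timestamps.hour.to_numpy()
    t_rec = schedule.lookup(age_day)["t_rec"].to_numpy()
    phase = np.cos(2 * np.pi * (hod - config.diurnal_peak_hour) / 24.0)
    t = t_rec + config.region_t_offset.get(flock.region, 0.0)
    t = t + config.diurnal_amplitude * phase
    rh = config.rh_mean - config.rh_amplitude * phase

    night = np.isin(hod, list(NIGHT_HOURS))
    if config.cold_night_fraction > 0 and rng.random() < config.cold_night_fraction:
        scale = rng.uniform(0.0, 1.0)
        t = t - scale * config.cold_night_depression * night

    t = t + rng.normal(0.0, config.env_noise_sd, CYCLE_HOURS)
    rh = rh + rng.normal(0.0, config.rh_noise_sd, CYCLE_HOURS)

    # Controlled excursions: pinned exactly at target + dt (no ambient noise)
    # so the offset relative to the band is exactly what the excursion
    # says, not a noisy version of it.
    for exc in config.excursions:
        if rng.random() >= exc.fraction:
            continue
        eligible_hod = NIGHT_HOURS if exc.dt <= 0 else AFTERNOON_HOURS
        window = (hours >= exc.start_day * HOURS_PER_DAY) & (hours < exc.end_day * HOURS_PER_DAY)
        eligible = hours[window & np.isin(hod, list(eligible_hod))]
        n_hours = int(round(rng.uniform(exc.hours_min, exc.hours_max)))
        n_hours = min(n_hours, eligible.size)
        if n_hours > 0:
            idx = rng.choice(eligible, size=n_hours, replace=False)
            t[idx] = t_rec[idx] + exc.dt
            if exc.rh is not None:
                rh[idx] = exc.rh

    rh = np.clip(rh, *config.rh_clip)
    return pd.DataFrame({
        "timestamp": timestamps, "hour_of_age": hours, "age_day": age_day,
        "t": t, "rh": rh,
    })


def gen_env_series(config: GeneratorConfig, flocks: pd.DataFrame | None = None,
                   farms: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate hourly two-sensor environment records for every flock.

    Returns a long frame with columns farm_id, house_id, sensor_id,
    timestamp, t, rh — one row per (house, hour, sensor); ``n_flocks * 840``
    house-hours before fault injection.
    """
    config.validate()
    layout = _seed_layout(config)
    if farms is None:
        farms = gen_farm_attributes(config, layout["farm"])
    if flocks is None:
        flocks = gen_flocks(config, farms, layout["flock"])
    schedule = config.schedule()
    frames = []
    for i, flock in enumerate(flocks.itertuples(index=False)):
        rng = np.random.default_rng(layout["env"][i])
        truth = _truth_series(config, flock, schedule, rng)
        for s in range(config.n_sensors):
            t_obs = truth["t"].to_numpy() + rng.normal(0.0, config.sensor_noise_sd, CYCLE_HOURS)
            rh_obs = truth["rh"].to_numpy() + rng.normal(0.0, config.sensor_noise_sd, CYCLE_HOURS)
            frames.append(pd.DataFrame({
                "farm_id": flock.farm_id,
                "house_id": flock.house_id,
                "sensor_id": f"S{s}",
                "timestamp": truth["timestamp"],
                "t": t_obs,
                "rh": np.clip(rh_obs, 0.0, 100.0),
            }))
    return pd.concat(frames, ignore_index=True)


def inject_faults(env: pd.DataFrame, config: GeneratorConfig,
                  rng: np.random.Generator | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a ``fault_rate`` fraction of houses with missing or outlier hours.

    Returns ``(env', manifest)``; the manifest lists each injected fault.
    Half the faulty houses lose 10-50 house-hours (both sensors), the other
    half get a physically impossible temperature burst (80 degC).
    """
    config.validate()
    if rng is None:
        rng = _seed_layout(config)["fault"]
    if config.fault_rate == 0:
        return env, pd.DataFrame(columns=["house_id", "fault", "n_hours"])
    houses = env["house_id"].unique()
    n_fault = int(round(config.fault_rate * len(houses)))
    faulty = rng.choice(houses, size=n_fault, replace=False)
    env = env.copy()
    manifest = []
    for house in faulty:
        mask = env["house_id"] == house
        hours = env.loc[mask, "timestamp"].unique()
        if rng.random() < 0.5:
            k = int(rng.integers(10, 51))
            dropped = rng.choice(hours, size=min(k, len(hours)), replace=False)
            env = env[~(mask & env["timestamp"].isin(dropped))]
            manifest.append({"house_id": house, "fault": "missing_hours", "n_hours": len(dropped)})
        else:
            k = int(rng.integers(1, 6))
            bad = rng.choice(hours, size=min(k, len(hours)), replace=False)
            env.loc[mask & env["timestamp"].isin(bad), "t"] = 80.0
            manifest.append({"house_id": house, "fault": "outlier_t80", "n_hours": len(bad)})
    return env.reset_index(drop=True), pd.DataFrame(manifest)


def _exposure_for_generation(env: pd.DataFrame, flocks: pd.DataFrame,
                             schedule: TargetSchedule) -> dict[str, pd.DataFrame]:
    """Per-flock exposure tables over all standard windows (no QC).

    Generation intentionally uses the same averaging/alignment/counting code
    path as the analysis, so configured slopes are exactly recoverable.
    """
    hourly = average_sensors(env)
    by_house = dict(tuple(hourly.groupby("house_id", sort=False)))
    out = {}
    for flock in flocks.itertuples(index=False):
        house = by_house.get(flock.house_id)
        if house is None or house.empty:
            continue
        series = align_age(house, flock.placement)
        if series.empty:
            continue
        exp = compute_exposure(series, schedule, flock.flock_id)
        out[flock.flock_id] = exp.set_index(["kind", "start_day", "end_day"]).sort_index()
    return out


def gen_performance(env: pd.DataFrame, flocks: pd.DataFrame,
                    schedule: TargetSchedule, config: GeneratorConfig,
                    farms: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate weekly performance records driven by exposure hours.

    BW gain is the BW difference between consecutive weekly weighings (the
    first week uses the day-old chick weight), and cumulative mortality is
    the running sum of weekly mortality, so records are internally
    consistent by construction.
    """
    config.validate()
    layout = _seed_layout(config)
    perf_seeds = layout["perf"]
    farm_rng = np.random.default_rng(perf_seeds[-1])
    farm_ids = flocks["farm_id"].unique()
    farm_offsets = {
        fid: {resp: farm_rng.normal(0.0, sd) for resp, sd in config.farm_offset_sd.items()}
        for fid in sorted(farm_ids)
    }
    exposures = _exposure_for_generation(env, flocks, schedule)

    rows = []
    for i, flock in enumerate(flocks.itertuples(index=False)):
        rng = np.random.default_rng(perf_seeds[i])
        exp = exposures.get(flock.flock_id)
        if exp is None:
            continue

        def hours(eff: ExposureEffect) -> float:
            try:
                return float(exp.loc[(eff.kind, eff.start_day, eff.end_day), eff.band])
            except KeyError as err:
                raise ValueError(
                    f"effect references window {(eff.kind, eff.start_day, eff.end_day)}"
                    " not covered by the standard windows"
                ) from err

        off = farm_offsets[flock.farm_id]
        sex_sign = 1.0 if flock.sex == "male" else -1.0
        noise = config.response_noise_sd

        bw = {}
        fcr = {}
        wmort = {}
        for age in PERF_AGES:
            bw[age] = (config.bw_base[age]
                       + sex_sign * config.sex_bw_offset[age]
                       + off.get("bw", 0.0)
                       + rng.normal(0.0, noise.get("bw", 0.0)))
            fcr[age] = (config.fcr_base[age]
                        - sex_sign * config.sex_fcr_offset
                        + off.get("fcr", 0.0)
                        + rng.normal(0.0, noise.get("fcr", 0.0)))
            wmort[age] = (config.week_mortality_base[age]
                          + off.get("week_mortality", 0.0)
                          + rng.normal(0.0, noise.get("week_mortality", 0.0)))
        for eff in config.exposure_effects:
            h = hours(eff)
            if eff.response == "bw":
                bw[eff.age_day] += eff.slope * h
            elif eff.response == "fcr":
                fcr[eff.age_day] += eff.slope * h
            elif eff.response in ("week_mortality", "cum_mortality"):
                wmort[eff.age_day] += eff.slope * h
            else:
                raise ValueError(f"unknown response {eff.response!r}")

        cum = 0.0
        prev_bw = config.chick_weight
        for age in PERF_AGES:
            wmort[age] = max(wmort[age], 0.0)
            cum += wmort[age]
            rows.append({
                "flock_id": flock.flock_id,
                "age_day": age,
                "bw": bw[age],
                "bw_gain": bw[age] - prev_bw,
                "fcr": max(fcr[age], 0.5),
                "week_mortality": wmort[age],
                "cum_mortality": cum,
            })
            prev_bw = bw[age]
    return pd.DataFrame(rows)


def _truth_frame(config: GeneratorConfig) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in config.exposure_effects])


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic study under one config (deterministic)."""
    config = config or GeneratorConfig()
    config.validate()
    layout = _seed_layout(config)
    farms = gen_farm_attributes(config, layout["farm"])
    flocks = gen_flocks(config, farms, layout["flock"])
    env_clean = gen_env_series(config, flocks, farms)
    env, manifest = inject_faults(env_clean, config, layout["fault"])
    schedule = config.schedule()
    performance = gen_performance(env_clean, flocks, schedule, config, farms)
    return SyntheticDataset(
        env=env,
        flocks=flocks,
        farms=farms,
        performance=performance,
        truth=_truth_frame(config),
        fault_manifest=manifest,
        config=config,
    )
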