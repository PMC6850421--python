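"""Simplified cohort-based honey bee colony engine.

Bees are tracked as same-age cohorts per caste (worker, drone) from egg
through pupation into adulthood; adult workers switch from in-hive duty
to foraging at a configurable age.  Each simulated day runs a fixed
sequence: the pollen store ages, the queen lays, foragers collect nectar
and pollen from the landscape, the colony consumes honey and stored
pollen (recording per-class ingested doses), exposure mortality is
applied (adults daily; larvae once at pupation inside the development
step), cohorts develop and transition, background mortality acts, and a
daily output row is recorded.

Deposits age into edibility only the next day, which is why foraging
precedes consumption and the store advances first.  Colonies are never
flagged dead by a winter size threshold: runs always cover the full
horizon so that spring censuses remain comparable across treatments.

Cohort counts are real-valued with expected-value mortality by default;
a seeded binomial mode provides stochastic realism for replicate runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pollen as pollen_mod
from .dose_response import DoseResponseCurve, evaluate_mortality
from .foraging import (
    ForagingParams,
    WeatherDay,
    allocate_trips,
    collect_loads,
    foraging_hours,
    pollen_forager_share,
)
from .pollen import (
    DoseLedger,
    ExposureConfig,
    PollenStore,
    advance_day,
    conditional_increment,
    default_curves,
    deposit,
    draw_and_ingest,
)

__all__ = ["BeeCohort", "ColonyParams", "Colony", "lay_eggs", "simulate"]


@dataclass
class BeeCohort:
    """A same-age group of bees of one caste and stage."""

    caste: str  # "worker" | "drone"
    stage: str  # "egg" | "larva" | "pupa"
    age_in_stage: int  # -1 on the day of laying; development starts next day
    count: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass
class ColonyParams:
    """Demographic and energetic defaults for the colony engine.

    Stage durations follow the usual worker timetable (egg 3 d, larva
    6 d, pupa 12 d; drones 3/7/14); other rates are package defaults in
    the style of the parent colony model, all exposed to configuration.
    """

    # stage durations (days)
    egg_days: int = 3
    worker_larva_days: int = 6
    worker_pupa_days: int = 12
    drone_egg_days: int = 3
    drone_larva_days: int = 7
    drone_pupa_days: int = 14
    age_first_foraging: int = 21
    max_adult_age: int = 290
    # seasonal egg laying
    laying_max: float = 1600.0
    laying_season: tuple[int, int] = (60, 270)
    eggs_per_adult: float = 0.12
    drone_egg_frac: float = 0.04
    drone_season: tuple[int, int] = (100, 240)
    # background daily mortality per stage
    m_egg: float = 0.03
    m_larva: float = 0.01
    m_pupa: float = 0.001
    m_in_hive: float = 0.004
    m_forager_flight: float = 0.08
    m_adult_drone: float = 0.05
    # honey demand (g/bee/day)
    honey_g_in_hive: float = 0.012
    honey_g_forager: float = 0.035
    honey_g_larva: float = 0.06
    honey_g_drone: float = 0.02
    honey_cap_kg: float = 60.0
    # shortage penalties (extra daily mortality per unit shortage fraction)
    starvation_mortality: float = 0.3
    brood_pollen_penalty: float = 0.3
    # initial state (1 January)
    initial_adults: float = 9000.0
    initial_honey_kg: float = 25.0
    initial_pollen_g: float = 200.0

    def __post_init__(self) -> None:
        for name in ("egg_days", "worker_larva_days", "worker_pupa_days",
                     "drone_egg_days", "drone_larva_days", "drone_pupa_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("m_egg", "m_larva", "m_pupa", "m_in_hive",
                     "m_forager_flight", "m_adult_drone"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def lay_eggs(day_of_year: int, params: ColonyParams, adult_count: float) -> tuple[float, float]:
    """Daily worker and drone egg numbers from the seasonal laying curve.

    A half-sine over the laying season peaks at the configured maximum,
    capped by nurse capacity (``eggs_per_adult`` per adult worker).
    Drone eggs are a small fraction during the drone season.
    """
    if not 1 <= day_of_year <= 365:
        raise ValueError("day_of_year must be in [1, 365]")
    start, end = params.laying_season
    if not start < day_of_year < end:
        return 0.0, 0.0
    base = params.laying_max * math.sin(math.pi * (day_of_year - start) / (end - start))
    eggs = max(0.0, min(base, params.eggs_per_adult * adult_count))
    ds, de = params.drone_season
    drone = eggs * params.drone_egg_frac if ds <= day_of_year <= de else 0.0
    return eggs - drone, drone


class _AdultPop:
    """Adult cohorts of one caste as struct-of-arrays (one per emergence day)."""

    def __init__(self) -> None:
        self.emergence_day = np.zeros(0, dtype=int)
        self.count = np.zeros(0)
        self.pstar_acute = np.zeros(0)
        self.pstar_chronic = np.zeros(0)

    def add(self, emergence_day: int, count: float, g_acute: float, g_chronic: float) -> None:
        self.emergence_day = np.append(self.emergence_day, emergence_day)
        self.count = np.append(self.count, count)
        self.pstar_acute = np.append(self.pstar_acute, g_acute)
        self.pstar_chronic = np.append(self.pstar_chronic, g_chronic)

    def ages(self, day: int) -> np.ndarray:
        return day - self.emergence_day

    def prune(self, day: int, max_age: int) -> None:
        keep = (self.count > 1e-9) & (self.ages(day) <= max_age)
        if not keep.all():
            self.emergence_day = self.emergence_day[keep]
            self.count = self.count[keep]
            self.pstar_acute = self.pstar_acute[keep]
            self.pstar_chronic = self.pstar_chronic[keep]

    @property
    def total(self) -> float:
        return float(self.count.sum())


class Colony:
    """Full colony state: brood cohorts, adults, queen, stores, ledgers."""

    def __init__(
        self,
        params: ColonyParams,
        exposure: ExposureConfig,
        curves: dict[str, DoseResponseCurve],
    ) -> None:
        self.params = params
        self.exposure = exposure
        self.curves = curves
        self.brood: list[BeeCohort] = []
        self.workers = _AdultPop()
        self.drones = _AdultPop()
        self.honey_kg = params.initial_honey_kg
        self.store = PollenStore()
        if params.initial_pollen_g > 0:
            deposit(self.store, params.initial_pollen_g, 0.0, source_patch="initial")
            advance_day(self.store)  # make the starting pollen edible
        self.ledgers = {
            cls: DoseLedger()
            for cls in ("worker_larva", "drone_larva", "in_hive", "forager", "adult_drone")
        }
        g_a = curves["adult_acute"].background
        g_c = curves["adult_chronic"].background
        # overwintered adults, emergence days before the simulation start
        ages = np.linspace(40, 140, 6).round().astype(int)
        for age in ages:
            self.workers.add(1 - int(age), params.initial_adults / len(ages), g_a, g_c)

    # -- convenience counts ------------------------------------------------
    def worker_split(self, day: int) -> tuple[float, float]:
        ages = self.workers.ages(day)
        in_hive = float(self.workers.count[ages < self.params.age_first_foraging].sum())
        foragers = float(self.workers.count[ages >= self.params.age_first_foraging].sum())
        return in_hive, foragers

    def stage_count(self, caste: str, stage: str) -> float:
        return sum(c.count for c in self.brood if c.caste == caste and c.stage == stage)


def _apply_mortality(count, p, stochastic: bool, rng) -> float:
    if p <= 0:
        return count
    if stochastic:
        return float(count - pollen_mod._stochastic_deaths(count, p, rng))
    return count * (1.0 - p)


class Simulation:
    """Daily orchestration of one colony in one landscape under one scenario."""

    def __init__(
        self,
        landscape,
        weather: list[WeatherDay],
        scenario,
        residue_level: float,
        seed: int,
        params: ColonyParams | None = None,
        exposure: ExposureConfig | None = None,
        curves: dict[str, DoseResponseCurve] | None = None,
        foraging_params: ForagingParams | None = None,
        stochastic: bool = True,
        exposure_effects_enabled: bool = True,
    ) -> None:
        self.landscape = landscape
        self.weather = weather
        self.scenario = scenario
        self.level = residue_level
        self.params = params or ColonyParams()
        self.exposure = exposure or ExposureConfig()
        self.curves = curves or default_curves(self.exposure)
        self.fparams = foraging_params or ForagingParams()
        self.stochastic = stochastic
        self.exposure_effects_enabled = exposure_effects_enabled
        self.rng = np.random.default_rng(seed)
        self.colony = Colony(self.params, self.exposure, self.curves)
        landscape.set_gathering_times(
            crop_pollen_s=scenario.gather_pollen_crop_s,
            crop_nectar_s=scenario.gather_nectar_crop_s,
            semi_natural_pollen_s=scenario.gather_pollen_sn_s,
            semi_natural_nectar_s=scenario.gather_nectar_sn_s,
        )
        self.day = 0
        self.rows: list[dict] = []
        self._last_dose_day = -(10**9)  # fast path: skip exposure math when clean

    # -- steps -------------------------------------------------------------
    def _forage(self, day_of_year: int, hours: float) -> tuple[float, float, float]:
        col = self.colony
        _, foragers = col.worker_split(self.day)
        view = self.landscape.day_view(
            day_of_year,
            self.level,
            discount=self.landscape.discounts(
                self.fparams.distance_half_m, self.fparams.distance_exponent
            ),
        )
        demand = self._pollen_demand_total()
        # collection capacity if all forager-seconds went to pollen trips,
        # at a typical mid-range trip time
        typical_tt = 2.0 * 500.0 / self.fparams.flight_speed_ms + 600.0 + self.fparams.handling_s
        capacity = foragers * hours * 3600.0 / typical_tt * self.fparams.pollen_load_g
        share = pollen_forager_share(col.store.total_mass, demand, capacity, self.fparams)
        p_trips, n_trips = allocate_trips(foragers, view, hours, self.fparams, share)
        sugar_kg, deposits = collect_loads(p_trips, n_trips, view, self.fparams)
        col.honey_kg = min(
            col.honey_kg + sugar_kg * self.fparams.honey_per_sugar,
            self.params.honey_cap_kg,
        )
        collected = 0.0
        test_field = 0.0
        for patch_id, mass, conc in deposits:
            deposit(col.store, mass, conc, source_patch=patch_id)
            collected += mass
            if (
                self.landscape.central_index is not None
                and patch_id == self.landscape.ids[self.landscape.central_index]
            ):
                test_field += mass
        return sugar_kg, collected, test_field

    def _pollen_demand_total(self) -> float:
        col, ex = self.colony, self.exposure
        in_hive, foragers = col.worker_split(self.day)
        return (
            ex.worker_larva_g * col.stage_count("worker", "larva")
            + ex.drone_larva_g * col.stage_count("drone", "larva")
            + ex.in_hive_g * in_hive
            + ex.forager_g * foragers
            + ex.adult_drone_g * col.drones.total
        )

    def _consume_and_feed(self, day_of_year: int, flight_day: bool) -> tuple[float, float]:
        col, p, ex = self.colony, self.params, self.exposure
        in_hive, foragers = col.worker_split(self.day)
        larvae_w = col.stage_count("worker", "larva")
        larvae_d = col.stage_count("drone", "larva")

        # foragers burn flight-level honey only on days they actually fly
        forager_honey = p.honey_g_forager if flight_day else p.honey_g_in_hive
        demand_kg = (
            p.honey_g_in_hive * in_hive
            + forager_honey * foragers
            + p.honey_g_larva * (larvae_w + larvae_d)
            + p.honey_g_drone * col.drones.total
        ) / 1000.0
        if col.honey_kg >= demand_kg:
            col.honey_kg -= demand_kg
            starvation = 0.0
        else:
            starvation = 1.0 - col.honey_kg / demand_kg if demand_kg > 0 else 0.0
            col.honey_kg = 0.0

        if self.scenario.harvest and day_of_year == self.scenario.harvest_day:
            col.honey_kg = min(col.honey_kg, self.scenario.harvest_leave_kg)
        if self.scenario.feeding and col.honey_kg < self.scenario.feeding_floor_kg:
            col.honey_kg = self.scenario.feeding_top_kg

        demands = {
            "worker_larva": (ex.worker_larva_g, larvae_w),
            "drone_larva": (ex.drone_larva_g, larvae_d),
            "in_hive": (ex.in_hive_g, in_hive),
            "forager": (ex.forager_g, foragers),
            "adult_drone": (ex.adult_drone_g, col.drones.total),
        }
        doses, shortfall = draw_and_ingest(col.store, demands, col.ledgers)
        total = sum(rate * n for rate, n in demands.values())
        shortfall_frac = shortfall / total if total > 0 else 0.0
        if any(d > 0 for d in doses.values()):
            self._last_dose_day = self.day
        return starvation, shortfall_frac

    # -- exposure mortality ------------------------------------------------
    def _ledger_window(self, ledger: DoseLedger, k: int) -> np.ndarray:
        """Last k daily entries as an array, zero-padded at the front."""
        out = np.zeros(k)
        seg = ledger.doses[max(0, self.day - k) : self.day]
        if seg:
            out[k - len(seg):] = seg
        return out

    def _adult_exposure(self, pop: _AdultPop, caste: str) -> None:
        acute, chronic = self.curves["adult_acute"], self.curves["adult_chronic"]
        k = chronic.window_days
        if self.day - self._last_dose_day >= k or len(pop.count) == 0:
            return  # no residue in any window: curves sit at background
        if caste == "worker":
            inh = self._ledger_window(self.colony.ledgers["in_hive"], k)
            for_ = self._ledger_window(self.colony.ledgers["forager"], k)
            days = np.arange(self.day - k + 1, self.day + 1)
            ages = days[None, :] - pop.emergence_day[:, None]
            aff = self.params.age_first_foraging
            dose = np.where(
                (ages >= 0) & (ages < aff),
                inh[None, :],
                np.where(ages >= aff, for_[None, :], 0.0),
            )
        else:
            drone_hist = self._ledger_window(self.colony.ledgers["adult_drone"], k)
            days = np.arange(self.day - k + 1, self.day + 1)
            ages = days[None, :] - pop.emergence_day[:, None]
            dose = np.where(ages >= 0, drone_hist[None, :], 0.0)
        d_chronic = dose.sum(axis=1)
        d_acute = dose[:, -acute.window_days:].sum(axis=1)
        p_a = np.asarray(evaluate_mortality(acute, d_acute))
        p_c = np.asarray(evaluate_mortality(chronic, d_chronic))
        h_a = conditional_increment(p_a, pop.pstar_acute)
        h_c = conditional_increment(p_c, pop.pstar_chronic)
        pop.pstar_acute = np.maximum(pop.pstar_acute, p_a)
        pop.pstar_chronic = np.maximum(pop.pstar_chronic, p_c)
        h = 1.0 - (1.0 - h_a) * (1.0 - h_c)
        if not np.any(h > 0):
            return
        if self.stochastic:
            n = np.floor(pop.count).astype(int)
            frac = pop.count - n
            deaths = self.rng.binomial(n, h) + frac * h
            pop.count = pop.count - deaths
        else:
            pop.count = pop.count * (1.0 - h)

    def _larval_pupation_survivors(self, cohort: BeeCohort) -> float:
        curve = self.curves["larval_chronic"]
        ledger_name = "worker_larva" if cohort.caste == "worker" else "drone_larva"
        larva_days = (
            self.params.worker_larva_days
            if cohort.caste == "worker"
            else self.params.drone_larva_days
        )
        window = min(curve.window_days, larva_days)
        dose = float(self._ledger_window(self.colony.ledgers[ledger_name], window).sum())
        p = evaluate_mortality(curve, dose)
        h = max(0.0, (p - curve.background) / (1.0 - curve.background))
        return _apply_mortality(cohort.count, h, self.stochastic, self.rng)

    # -- development -------------------------------------------------------
    def _develop_and_transition(self) -> None:
        col, p = self.colony, self.params
        g_a = self.curves["adult_acute"].background
        g_c = self.curves["adult_chronic"].background
        new_brood: list[BeeCohort] = []
        for cohort in col.brood:
            cohort.age_in_stage += 1
            caste = cohort.caste
            if cohort.stage == "egg":
                dur = p.egg_days if caste == "worker" else p.drone_egg_days
                if cohort.age_in_stage >= dur:
                    cohort.stage, cohort.age_in_stage = "larva", 0
            elif cohort.stage == "larva":
                dur = p.worker_larva_days if caste == "worker" else p.drone_larva_days
                if cohort.age_in_stage >= dur:
                    if self.exposure_effects_enabled:
                        cohort.count = self._larval_pupation_survivors(cohort)
                    cohort.stage, cohort.age_in_stage = "pupa", 0
            elif cohort.stage == "pupa":
                dur = p.worker_pupa_days if caste == "worker" else p.drone_pupa_days
                if cohort.age_in_stage >= dur:
                    if cohort.count > 1e-9:
                        pop = col.workers if caste == "worker" else col.drones
                        pop.add(self.day, cohort.count, g_a, g_c)
                    continue  # emerged: leaves the brood list
            if cohort.count > 1e-9:
                new_brood.append(cohort)
        col.brood = new_brood
        col.workers.prune(self.day, p.max_adult_age)
        col.drones.prune(self.day, p.max_adult_age)

    def _background_mortality(self, starvation: float, shortfall_frac: float, flight_day: bool) -> None:
        col, p, sc = self.colony, self.params, self.scenario
        starv = p.starvation_mortality * starvation
        brood_extra = (
            p.brood_pollen_penalty * shortfall_frac + sc.mite_proxy_brood + starv
        )
        rates = {
            "egg": p.m_egg + starv,
            "larva": p.m_larva + brood_extra,
            "pupa": p.m_pupa + sc.mite_proxy_brood,
        }
        for cohort in col.brood:
            cohort.count = _apply_mortality(
                cohort.count, min(1.0, rates[cohort.stage]), self.stochastic, self.rng
            )
        col.brood = [c for c in col.brood if c.count > 1e-9]
        ages = col.workers.ages(self.day)
        forager = ages >= p.age_first_foraging
        m = np.where(
            forager & flight_day, p.m_forager_flight, p.m_in_hive + sc.mite_proxy_in_hive
        )
        m = np.minimum(1.0, m + starv)
        if self.stochastic:
            n = np.floor(col.workers.count).astype(int)
            frac = col.workers.count - n
            col.workers.count = col.workers.count - (self.rng.binomial(n, m) + frac * m)
        else:
            col.workers.count = col.workers.count * (1.0 - m)
        md = min(1.0, p.m_adult_drone + starv)
        if self.stochastic:
            n = np.floor(col.drones.count).astype(int)
            frac = col.drones.count - n
            col.drones.count = col.drones.count - (self.rng.binomial(n, md) + frac * md)
        else:
            col.drones.count = col.drones.count * (1.0 - md)

    # -- the day -----------------------------------------------------------
    def daily_step(self) -> dict:
        self.day += 1
        t = self.day
        if t > len(self.weather):
            raise ValueError(f"no weather available for simulation day {t}")
        day_of_year = (t - 1) % 365 + 1
        w = self.weather[t - 1]
        col, p = self.colony, self.params

        # 1. pollen store ages (yesterday's collection becomes edible)
        advance_day(col.store)

        # 2. egg laying (age -1: development counts from tomorrow, so an
        # egg laid on day t emerges as an adult on day t + 21)
        worker_eggs, drone_eggs = lay_eggs(day_of_year, p, col.workers.total)
        if worker_eggs > 0:
            col.brood.append(BeeCohort("worker", "egg", -1, worker_eggs))
        if drone_eggs > 0:
            col.brood.append(BeeCohort("drone", "egg", -1, drone_eggs))

        # 3. foraging and deposition
        hours = foraging_hours(w)
        sugar_kg, collected, test_field = (
            self._forage(day_of_year, hours) if hours > 0 else (0.0, 0.0, 0.0)
        )

        # 4. consumption, dose recording, beekeeping
        starvation, shortfall_frac = self._consume_and_feed(day_of_year, hours > 0)

        # 5. adult exposure mortality (larval applied at pupation in step 6)
        if self.exposure_effects_enabled:
            self._adult_exposure(col.workers, "worker")
            self._adult_exposure(col.drones, "drone")

        # 6. development and transitions
        self._develop_and_transition()

        # 7. background mortality
        self._background_mortality(starvation, shortfall_frac, hours > 0)

        # 8. record
        in_hive, foragers = col.worker_split(t)
        row = {
            "day": t,
            "day_of_year": day_of_year,
            "adults": in_hive + foragers,
            "in_hive": in_hive,
            "foragers": foragers,
            "adult_drones": col.drones.total,
            "eggs": col.stage_count("worker", "egg") + col.stage_count("drone", "egg"),
            "larvae": col.stage_count("worker", "larva") + col.stage_count("drone", "larva"),
            "pupae": col.stage_count("worker", "pupa") + col.stage_count("drone", "pupa"),
            "honey_kg": col.honey_kg,
            "pollen_store_g": col.store.total_mass,
            "pollen_collected_g": collected,
            "pollen_from_test_field_g": test_field,
            "pollen_shortfall_frac": shortfall_frac,
            "foraging_hours": hours,
            "dose_in_hive_ng": col.ledgers["in_hive"].doses[-1],
            "dose_forager_ng": col.ledgers["forager"].doses[-1],
            "dose_worker_larva_ng": col.ledgers["worker_larva"].doses[-1],
        }
        self.rows.append(row)
        return row

    def run(self, horizon: int = 480) -> pd.DataFrame:
        for _ in range(horizon):
            self.daily_step()
        return pd.DataFrame(self.rows)


def simulate(
    landscape,
    weather: list[WeatherDay],
    scenario,
    residue_level: float,
    seed: int,
    horizon: int = 480,
    **kwargs,
) -> pd.DataFrame:
    """Run one seeded colony simulation and return its daily time series."""
    sim = Simulation(landscape, weather, scenario, residue_level, seed, **kwargs)
    return sim.run(horizon)
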