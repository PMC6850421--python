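"""Scenario definitions and factorial in-silico experiment execution.

Two standard scenarios are provided.  The *baseline* scenario represents
good colony conditions: no beekeeping interventions and pollen/nectar
gathering times of 600/1200 s everywhere.  The *stress* scenario lowers
colony condition: gathering times double to 1200/2400 s on semi-natural
covers (lower-quality resource patches), honey is harvested and colonies
are fed by a beekeeper, and a parasite/virus burden is approximated by
elevated background in-hive and brood mortality (the mite proxy).

A design enumerates scenario x site x residue level x repetition cells
over the 480-day horizon (365 days plus 115 days of the following
spring, reusing year-1 weather).  The same repetition index shares one
random seed across residue levels within a scenario and site, so that
exposed runs pair exactly with their control for effect metrics.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .colony import ColonyParams, simulate
from .landscape import (
    Landscape,
    WeatherParams,
    build_landscape,
    composition_metrics,
    synthesize_landscape,
    synthesize_weather,
)

__all__ = [
    "Scenario",
    "SyntheticSite",
    "Design",
    "RunSpec",
    "baseline_scenario",
    "stress_scenario",
    "derive_seed",
    "enumerate_runs",
    "run_experiment",
    "DEFAULT_RESIDUE_LEVELS",
    "CENSUS_DAYS",
]

#: Residue levels (ng active ingredient / g pollen) of the standard design:
#: control, proposed colony-level pollen LOAEC, proposed nectar NOAEC,
#: highest field-measured concentration, adult 48-h LC100, larval 21-d LC50.
DEFAULT_RESIDUE_LEVELS = (0.0, 12.2, 19.0, 39.9, 200.0, 2800.0)

#: Census days on the 365-day calendar: 21 Oct (day 294) and 1 Apr of
#: year 2 (day 365 + 91 = 456).
CENSUS_DAYS = (294, 456)

HORIZON_DAYS = 480


@dataclass(frozen=True)
class Scenario:
    """Colony-condition scenario: gathering times, beekeeping, mite proxy."""

    name: str
    gather_pollen_crop_s: float = 600.0
    gather_nectar_crop_s: float = 1200.0
    gather_pollen_sn_s: float = 600.0
    gather_nectar_sn_s: float = 1200.0
    harvest: bool = False
    harvest_day: int = 240
    harvest_leave_kg: float = 10.0
    feeding: bool = False
    feeding_floor_kg: float = 2.0
    feeding_top_kg: float = 5.0
    mite_proxy_in_hive: float = 0.0
    mite_proxy_brood: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gather_pollen_crop_s", "gather_nectar_crop_s",
                     "gather_pollen_sn_s", "gather_nectar_sn_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def baseline_scenario() -> Scenario:
    return Scenario(name="baseline")


def stress_scenario() -> Scenario:
    return Scenario(
        name="stress",
        gather_pollen_sn_s=1200.0,
        gather_nectar_sn_s=2400.0,
        harvest=True,
        feeding=True,
        mite_proxy_in_hive=0.008,
        mite_proxy_brood=0.012,
    )


SCENARIOS = {"baseline": baseline_scenario, "stress": stress_scenario}


@dataclass(frozen=True)
class SyntheticSite:
    """Specification of one synthetic landscape in a design."""

    name: str
    semi_natural: float
    other_crop: float
    alfalfa_buckwheat: float = 0.0
    central_field_ha: float = 10.0

    def fractions(self) -> dict[str, float]:
        return {
            "semi_natural": self.semi_natural,
            "other_crop": self.other_crop,
            "alfalfa_buckwheat": self.alfalfa_buckwheat,
        }


def default_sites(n: int = 4) -> list[SyntheticSite]:
    """Synthetic sites spanning 20-80% semi-natural cover (corn-belt style)."""
    sn_levels = [0.2, 0.4, 0.6, 0.8][:n]
    return [
        SyntheticSite(
            name=f"SYN-{int(100 * sn):02d}",
            semi_natural=sn,
            other_crop=round(0.92 - sn, 2),
            alfalfa_buckwheat=0.03,
        )
        for sn in sn_levels
    ]


@dataclass
class Design:
    """A factorial simulation design."""

    scenarios: tuple[str, ...] = ("baseline", "stress")
    sites: tuple[SyntheticSite, ...] = tuple(default_sites())
    residue_levels: tuple[float, ...] = DEFAULT_RESIDUE_LEVELS
    repetitions: int = 20
    base_seed: int = 0
    horizon: int = HORIZON_DAYS
    census_days: tuple[int, ...] = CENSUS_DAYS
    stochastic: bool = True

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if any(lv < 0 for lv in self.residue_levels):
            raise ValueError("residue levels must be >= 0")


@dataclass(frozen=True)
class RunSpec:
    """One design cell with its derived seed."""

    scenario: str
    site: str
    level: float
    rep: int
    seed: int

    @property
    def key(self) -> str:
        return f"{self.scenario}_{self.site}_L{self.level:g}_r{self.rep}"


def derive_seed(base_seed: int, *parts) -> int:
    """Deterministic seed below 2**31 from a base seed and string-able parts."""
    text = "|".join([str(base_seed), *map(str, parts)])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def enumerate_runs(design: Design) -> list[RunSpec]:
    """All design cells in a fixed order with paired seeds.

    The colony seed depends on (scenario, site, rep) but *not* on the
    residue level, so the same repetition at different levels shares all
    stochastic draws with its control and effect metrics pair exactly.
    """
    runs = []
    for scen, site, level, rep in itertools.product(
        design.scenarios, design.sites, design.residue_levels,
        range(design.repetitions),
    ):
        runs.append(RunSpec(
            scenario=scen,
            site=site.name,
            level=level,
            rep=rep,
            seed=derive_seed(design.base_seed, scen, site.name, rep),
        ))
    return runs


def build_site_inputs(design: Design) -> dict[str, dict]:
    """Synthesize landscape and weather once per site (shared by all cells)."""
    inputs = {}
    for site in design.sites:
        grid = synthesize_landscape(
            derive_seed(design.base_seed, "landscape", site.name),
            site.fractions(),
            central_field_ha=site.central_field_ha,
        )
        year = synthesize_weather(derive_seed(design.base_seed, "weather", site.name))
        inputs[site.name] = {
            "grid": grid,
            "landscape": build_landscape(grid),
            "weather": list(year) + list(year[: design.horizon - 365]),
            "composition": composition_metrics(grid),
        }
    return inputs


def run_experiment(
    design: Design,
    outdir: str | Path | None = None,
    progress=None,
    site_inputs: dict | None = None,
    **simulate_kwargs,
) -> dict[str, pd.DataFrame]:
    """Execute every cell of a design; returns ``{cell key: RunRecord}``.

    Each cell is seeded independently, so execution order cannot affect
    any result.  With ``outdir`` set, each run is written to CSV as it
    completes and cells whose CSV already exists are loaded instead of
    recomputed (interrupt-and-resume).  Failures are collected and
    re-raised at the end with their cell keys; completed results are
    preserved.
    """
    site_inputs = site_inputs or build_site_inputs(design)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    failures: list[tuple[str, Exception]] = []
    runs = enumerate_runs(design)
    for spec in runs:
        path = out / f"{spec.key}.csv" if out is not None else None
        if path is not None and path.exists():
            results[spec.key] = pd.read_csv(path)
            continue
        inp = site_inputs[spec.site]
        try:
            record = simulate(
                inp["landscape"],
                inp["weather"],
                SCENARIOS[spec.scenario](),
                spec.level,
                spec.seed,
                horizon=design.horizon,
                stochastic=design.stochastic,
                **simulate_kwargs,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((spec.key, exc))
            continue
        results[spec.key] = record
        if path is not None:
            record.to_csv(path, index=False)
        if progress is not None:
            progress(spec, record)
    if out is not None:
        index = pd.DataFrame([
            {"key": s.key, "scenario": s.scenario, "site": s.site,
             "level": s.level, "rep": s.rep, "seed": s.seed}
            for s in runs
        ])
        index.to_csv(out / "index.csv", index=False)
    if failures:
        keys = ", ".join(k for k, _ in failures)
        raise RuntimeError(f"runs failed: {keys}") from failures[0][1]
    return results
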