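"""Response metrics and summary tables for simulation experiments.

Two response metrics quantify outcomes:

* *Colony-level effect* — adult bees in an exposed run divided by adult
  bees in its seed-paired control run at a census day, times 100.
* *Test-field pollen share* — pollen collected from the central test
  cornfield during corn tasseling (days 203-216) as a percentage of all
  pollen collected over the same window.

Summaries (per-site means with 90th-percentile intervals of the pollen
share in control runs, per-level effect distributions, and a tidy long
table joining landscape composition) are exported for external
statistics; the mixed-effects regression itself is not re-implemented
here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landscape import TASSELING_WINDOW

__all__ = [
    "colony_level_effect",
    "test_field_pollen_pct",
    "effect_table",
    "summarize_effects",
]


def _adults_on(record: pd.DataFrame, census_day: int) -> float:
    sel = record.loc[record["day"] == census_day, "adults"]
    if sel.empty:
        raise ValueError(f"run record has no day {census_day}")
    return float(sel.iloc[0])


def colony_level_effect(
    exposed: pd.DataFrame, control: pd.DataFrame, census_day: int
) -> float:
    """Percent of control adult bees present in the exposed colony.

    Both records must come from runs sharing scenario, site and seed.
    Raises if the control colony has no adults on the census day (the
    metric is undefined there).
    """
    adults_c = _adults_on(control, census_day)
    adults_e = _adults_on(exposed, census_day)
    if adults_c <= 0:
        raise ZeroDivisionError(
            f"control run has no adult bees on day {census_day}; effect undefined"
        )
    return 100.0 * adults_e / adults_c


def test_field_pollen_pct(
    record: pd.DataFrame, window: tuple[int, int] = TASSELING_WINDOW
) -> float:
    """Percent of tasseling-window pollen collected from the test field.

    Returns NaN (flagged, not silent zero) when no pollen at all was
    collected in the window.
    """
    lo, hi = window
    sel = record[(record["day"] >= lo) & (record["day"] <= hi)]
    total = float(sel["pollen_collected_g"].sum())
    if total <= 0:
        return float("nan")
    return 100.0 * float(sel["pollen_from_test_field_g"].sum()) / total


def _parse_key(key: str) -> dict:
    scenario, rest = key.split("_", 1)
    site, level_s, rep_s = rest.rsplit("_", 2)
    return {
        "scenario": scenario,
        "site": site,
        "level": float(level_s[1:]),
        "rep": int(rep_s[1:]),
    }


def effect_table(
    results: dict[str, pd.DataFrame],
    census_days: tuple[int, ...] = (294, 456),
) -> pd.DataFrame:
    """Tidy table of effect % and pollen share % for every non-degenerate cell.

    ``results`` maps run keys (``scenario_site_Llevel_rrep``) to run
    records; each exposed run is paired with the control (level 0) of
    the same scenario, site and repetition.
    """
    meta = {k: _parse_key(k) for k in results}
    rows = []
    for key, record in results.items():
        m = meta[key]
        control_key = f"{m['scenario']}_{m['site']}_L0_r{m['rep']}"
        if control_key not in results:
            continue
        control = results[control_key]
        pollen_pct = test_field_pollen_pct(record)
        for day in census_days:
            rows.append({
                **m,
                "census_day": day,
                "effect_pct": colony_level_effect(record, control, day),
                "test_field_pollen_pct": pollen_pct,
                "adults": _adults_on(record, day),
                "control_adults": _adults_on(control, day),
            })
    return pd.DataFrame(rows)


def summarize_effects(
    results: dict[str, pd.DataFrame],
    compositions: dict[str, dict] | None = None,
    census_days: tuple[int, ...] = (294, 456),
) -> dict[str, pd.DataFrame]:
    """Summary tables: pollen collection by site, effects by level, long table.

    The pollen-share summary uses control runs only, so that residue
    effects on foraging cannot contaminate the exposure proxy.  Returns
    ``{"pollen_collection", "effects", "long"}`` DataFrames; the long
    table is regression-ready (site, rep, scenario, pollen %, and the
    landscape composition % if supplied).
    """
    table = effect_table(results, census_days)
    if table.empty:
        raise ValueError("no paired runs found in results")

    controls = table[(table["level"] == 0) & (table["census_day"] == census_days[0])]
    pollen = (
        controls.groupby(["scenario", "site"])["test_field_pollen_pct"]
        .agg(
            mean="mean",
            p05=lambda s: s.quantile(0.05),
            p95=lambda s: s.quantile(0.95),
            n="count",
        )
        .reset_index()
    )

    effects = (
        table.groupby(["scenario", "level", "census_day"])["effect_pct"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            mean="mean",
            n="count",
        )
        .reset_index()
    )

    long = controls[["scenario", "site", "rep", "test_field_pollen_pct"]].copy()
    if compositions:
        for col in ("semi_natural", "other_crop", "alfalfa_buckwheat"):
            long[f"pct_{col}"] = long["site"].map(
                {s: c.get(col, np.nan) for s, c in compositions.items()}
            )
    return {"pollen_collection": pollen, "effects": effects, "long": long}
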