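"""File formats, run configuration, and output manifests.

Everything on disk is inspectable text: land-cover grids are
whitespace-delimited integer rasters with a small header, tables are
CSV with fixed headers, configuration is YAML, and run outputs are one
CSV per run plus a JSON manifest with content digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dose_response import DoseResponseCurve
from .experiment import Design, SyntheticSite
from .foraging import WeatherDay
from .landscape import LandCoverClass, LandCoverGrid, default_class_table

__all__ = [
    "read_grid", "write_grid",
    "read_class_table", "write_class_table",
    "read_weather", "write_weather",
    "read_curves", "write_curves",
    "read_design",
    "RunConfig", "load_inputs", "write_outputs",
]


# ---------------------------------------------------------------------------
# Land-cover grid (plain text)
# ---------------------------------------------------------------------------

def write_grid(grid: LandCoverGrid, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"pixel_size_m {grid.pixel_size_m:g}",
        f"colony_pixel {grid.colony_rc[0]} {grid.colony_rc[1]}",
        "codes",
    ]
    lines += [" ".join(str(v) for v in row) for row in grid.codes]
    if grid.central_mask is not None:
        lines.append("central_mask")
        lines += [" ".join(str(int(v)) for v in row) for row in grid.central_mask]
    path.write_text("\n".join(lines) + "\n")


def read_grid(path: str | Path) -> LandCoverGrid:
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    header: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i] != "codes":
        key, _, value = lines[i].partition(" ")
        header[key] = value
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: missing 'codes' section")
    if "colony_pixel" not in header:
        raise ValueError(f"{path}: missing 'colony_pixel' header")
    i += 1
    rows = []
    while i < len(lines) and lines[i] != "central_mask":
        rows.append([int(v) for v in lines[i].split()])
        i += 1
    codes = np.array(rows, dtype=int)
    central = None
    if i < len(lines) and lines[i] == "central_mask":
        mask_rows = [[int(v) for v in ln.split()] for ln in lines[i + 1:]]
        central = np.array(mask_rows, dtype=bool)
    r, c = header["colony_pixel"].split()
    return LandCoverGrid(
        codes=codes,
        colony_rc=(int(r), int(c)),
        central_mask=central,
        pixel_size_m=float(header.get("pixel_size_m", 30.0)),
    )


# ---------------------------------------------------------------------------
# Class table, weather, curves
# ---------------------------------------------------------------------------

_CLASS_COLUMNS = [f.name for f in dataclasses.fields(LandCoverClass)]


def write_class_table(classes: dict[int, LandCoverClass], path: str | Path) -> None:
    rows = [dataclasses.asdict(c) for c in classes.values()]
    pd.DataFrame(rows, columns=_CLASS_COLUMNS).to_csv(path, index=False)


def read_class_table(path: str | Path) -> dict[int, LandCoverClass]:
    df = pd.read_csv(path)
    missing = set(_CLASS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        d = row.to_dict()
        d["sn_category"] = "" if pd.isna(d["sn_category"]) else str(d["sn_category"])
        d["pollen_only"] = bool(d["pollen_only"])
        d["code"] = int(d["code"])
        d["flower_start"] = int(d["flower_start"])
        d["flower_end"] = int(d["flower_end"])
        cls = LandCoverClass(**d)
        out[cls.code] = cls
    return out


def write_weather(days: list[WeatherDay], path: str | Path) -> None:
    pd.DataFrame(
        {
            "day": np.arange(1, len(days) + 1),
            "tmax_C": [w.tmax for w in days],
            "precip_mm": [w.precip for w in days],
            "day_length_h": [w.day_length for w in days],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_weather(path: str | Path) -> list[WeatherDay]:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"tmax_C", "precip_mm", "day_length_h"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        WeatherDay(tmax=float(r.tmax_C), precip=float(r.precip_mm),
                   day_length=float(r.day_length_h))
        for r in df.itertuples()
    ]


def write_curves(curves: dict[str, DoseResponseCurve], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({k: c.to_dict() for k, c in curves.items()}, sort_keys=True)
    )


def read_curves(path: str | Path) -> dict[str, DoseResponseCurve]:
    data = yaml.safe_load(Path(path).read_text())
    return {k: DoseResponseCurve.from_dict(v) for k, v in data.items()}


def read_design(path: str | Path) -> Design:
    data = yaml.safe_load(Path(path).read_text())
    kwargs = {}
    if "scenarios" in data:
        kwargs["scenarios"] = tuple(data["scenarios"])
    if "sites" in data:
        kwargs["sites"] = tuple(SyntheticSite(**s) for s in data["sites"])
    if "residue_levels" in data:
        kwargs["residue_levels"] = tuple(float(v) for v in data["residue_levels"])
    for key in ("repetitions", "base_seed", "horizon", "stochastic"):
        if key in data:
            kwargs[key] = data[key]
    return Design(**kwargs)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and settings for a single simulation run."""

    landscape_path: str
    weather_path: str
    class_table_path: str | None = None
    curves_path: str | None = None
    scenario: str = "baseline"
    residue_level: float = 0.0
    seed: int = 0
    horizon: int = 480
    outdir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class LoadedInputs:
    grid: LandCoverGrid
    class_table: dict[int, LandCoverClass]
    weather: list[WeatherDay]
    curves: dict[str, DoseResponseCurve] | None
    digest: str
    report: list[str]


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_inputs(config: RunConfig) -> LoadedInputs:
    """Load and cross-validate all inputs for a run.

    Every failed check is reported with the offending file and field;
    nothing is returned unless all checks pass (no partial loads).  The
    returned digest is a content hash over all input files, so identical
    fixtures always echo the same digest.
    """
    errors: list[str] = []
    report: list[str] = []
    hasher = hashlib.sha256()

    paths = {"landscape": Path(config.landscape_path), "weather": Path(config.weather_path)}
    if config.class_table_path:
        paths["class_table"] = Path(config.class_table_path)
    if config.curves_path:
        paths["curves"] = Path(config.curves_path)
    for name, p in paths.items():
        if not p.exists():
            errors.append(f"{name}: file not found: {p}")
    if errors:
        raise FileNotFoundError("; ".join(errors))
    for name in sorted(paths):
        hasher.update(paths[name].read_bytes())

    grid = read_grid(paths["landscape"])
    classes = (
        read_class_table(paths["class_table"])
        if "class_table" in paths
        else default_class_table()
    )
    weather = read_weather(paths["weather"])
    curves = read_curves(paths["curves"]) if "curves" in paths else None

    unknown = sorted(set(np.unique(grid.codes)) - set(classes))
    if unknown:
        errors.append(
            f"landscape {paths['landscape']}: codes missing from class table: {unknown}"
        )
    if len(weather) < min(config.horizon, 365):
        errors.append(
            f"weather {paths['weather']}: {len(weather)} days cannot cover a "
            f"{config.horizon}-day horizon (365 days are reused for year 2)"
        )
    if curves is not None:
        for name in ("larval_chronic", "adult_acute", "adult_chronic"):
            if name not in curves:
                errors.append(f"curves {paths['curves']}: missing endpoint {name}")
    if errors:
        raise ValueError("; ".join(errors))

    report.append(f"grid {grid.codes.shape[0]}x{grid.codes.shape[1]} pixels")
    report.append(f"{len(classes)} land-cover classes, {len(weather)} weather days")
    return LoadedInputs(
        grid=grid, class_table=classes, weather=weather, curves=curves,
        digest=hasher.hexdigest(), report=report,
    )


def extend_weather(weather: list[WeatherDay], horizon: int) -> list[WeatherDay]:
    """Apply the year-1 reuse rule: days beyond 365 repeat days 1 onward."""
    out = list(weather[:365])
    i = 0
    while len(out) < horizon:
        out.append(weather[i % 365])
        i += 1
    return out


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

RUN_COLUMNS = [
    "day", "day_of_year", "adults", "in_hive", "foragers", "adult_drones",
    "eggs", "larvae", "pupae", "honey_kg", "pollen_store_g",
    "pollen_collected_g", "pollen_from_test_field_g", "pollen_shortfall_frac",
    "foraging_hours", "dose_in_hive_ng", "dose_forager_ng",
    "dose_worker_larva_ng",
]


def write_outputs(
    records: dict[str, pd.DataFrame],
    tables: dict[str, pd.DataFrame] | None,
    outdir: str | Path,
    config_digest: str = "",
    seeds: dict[str, int] | None = None,
) -> dict:
    """Write run CSVs and summary tables with a JSON manifest.

    Column order of run CSVs is fixed; writing the same inputs twice
    produces identical files and manifests (idempotent).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for key in sorted(records):
        path = out / f"{key}.csv"
        records[key].reindex(columns=RUN_COLUMNS).to_csv(path, index=False)
        files[path.name] = _digest_file(path)
    for name in sorted(tables or {}):
        path = out / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        files[path.name] = _digest_file(path)
    manifest = {
        "n_runs": len(records),
        "files": files,
        "seeds": seeds or {},
        "config_digest": config_digest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
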