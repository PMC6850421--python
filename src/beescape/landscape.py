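"""Land-cover grids, foraging patches, resource calendars, and synthetic inputs.

A landscape is a 30-m land-cover raster centred on the colony, which sits
in the middle of a central test cornfield.  Adjacent pixels with the same
land-cover code (rook/4-connectivity by default) are merged into foraging
patches; the central field is always its own patch at distance 0, even
when adjacent corn pixels exist.  Excluded covers (open water, developed,
barren, non-bee crops) are dropped, as are patches below a minimum area.

Each patch carries a daily nectar (L) and pollen (g) availability
calendar.  Crop patches produce per-flower amounts times flower density
and area during their flowering window; corn and sorghum/millet are
pollen-only.  Semi-natural covers get a monthly per-square-metre resource
level by category, uniform within each month.  The central cornfield has
a residue schedule: the configured concentration (ng/g pollen), constant
over the corn tasseling window (days 203-216), zero otherwise.

Synthetic generators emulate corn-belt landscape compositions (a seeded
ring-mosaic of field-sized clustered regions hitting target cover
fractions with matched radial profiles across classes) and a temperate
season of daily weather (sinusoidal maximum temperature, seeded wet days,
day length from latitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .foraging import WeatherDay

__all__ = [
    "PIXEL_SIZE_M",
    "TASSELING_WINDOW",
    "LandCoverClass",
    "LandCoverGrid",
    "Patch",
    "Landscape",
    "PatchDayView",
    "WeatherParams",
    "default_class_table",
    "build_patches",
    "build_landscape",
    "resource_calendar",
    "composition_metrics",
    "synthesize_landscape",
    "synthesize_weather",
]

PIXEL_SIZE_M = 30.0
PIXEL_AREA_M2 = PIXEL_SIZE_M * PIXEL_SIZE_M

#: Corn tasseling (pollen shed): 22 July - 4 August on a 365-day calendar.
TASSELING_WINDOW = (203, 216)

#: Cumulative month-end day numbers, 365-day (non-leap) calendar.
_MONTH_ENDS = np.array([31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334, 365])

#: Monthly semi-natural resource base levels per m2 per day, Jan..Dec:
#: (nectar uL, pollen mg).  Scaled by the class category factor.
_SN_MONTHLY = np.array([
    (0, 0), (0, 0), (5, 1), (40, 8), (60, 12), (50, 10),
    (40, 8), (35, 7), (25, 5), (8, 2), (0, 0), (0, 0),
], dtype=float)

_SN_CATEGORY_FACTOR = {"low": 0.4, "medium": 1.0, "high": 1.6}
_SN_SUGAR_G_ML = 0.4


def day_to_month(day_of_year: int) -> int:
    """1-based month for a 1-based day of a 365-day year."""
    return int(np.searchsorted(_MONTH_ENDS, day_of_year)) + 1


@dataclass(frozen=True)
class LandCoverClass:
    """Parameters of one land-cover code.

    ``role`` is ``crop``, ``semi_natural`` or ``excluded``; ``category``
    is the analysis grouping (``other_crop``, ``alfalfa_buckwheat``,
    ``semi_natural`` or ``excluded``).  Crop resource production is
    per-flower per day times flower density over the flowering window;
    semi-natural covers use a monthly category level instead.
    """

    code: int
    name: str
    role: str
    category: str
    attractiveness: float = 1.0
    nectar_ul_per_flower: float = 0.0
    pollen_mg_per_flower: float = 0.0
    flower_density_m2: float = 0.0
    sugar_g_ml: float = 0.4
    flower_start: int = 0
    flower_end: int = 0
    pollen_only: bool = False
    sn_category: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("crop", "semi_natural", "excluded"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "crop" and not (
            1 <= self.flower_start <= 365 and self.flower_start <= self.flower_end <= 365
        ):
            raise ValueError(f"flowering window must lie within [1, 365] for {self.name}")
        if self.role == "semi_natural" and self.sn_category not in _SN_CATEGORY_FACTOR:
            raise ValueError(f"semi-natural class {self.name} needs a category")


def default_class_table() -> dict[int, LandCoverClass]:
    """Built-in land-cover table for corn-belt landscapes.

    Codes loosely follow cropland-raster conventions.  Per-flower
    production, densities and windows are documented package defaults
    (see docs/methods.md); beans and peas share one parameter set, as do
    sorghum and millet.
    """
    crops = [
        # code, name, category, attract, nectar uL/fl, pollen mg/fl, density /m2,
        # sugar g/mL, window, pollen_only
        LandCoverClass(1, "corn", "crop", "other_crop", 0.25, 0.0, 2.0, 8.0,
                       0.0, *TASSELING_WINDOW, pollen_only=True),
        LandCoverClass(4, "sorghum_millet", "crop", "other_crop", 0.25, 0.0, 0.4, 30.0,
                       0.0, 210, 240, pollen_only=True),
        LandCoverClass(5, "soybeans", "crop", "other_crop", 0.5, 0.1, 0.03, 250.0,
                       0.4, 182, 235),
        LandCoverClass(42, "beans_peas", "crop", "other_crop", 0.5, 0.2, 0.05, 100.0,
                       0.35, 170, 220),
        LandCoverClass(36, "alfalfa", "crop", "alfalfa_buckwheat", 1.0, 0.15, 0.04, 400.0,
                       0.4, 152, 258),
        LandCoverClass(39, "buckwheat", "crop", "alfalfa_buckwheat", 1.0, 0.3, 0.08, 300.0,
                       0.45, 182, 244),
    ]
    semi = [
        LandCoverClass(37, "hay_non_alfalfa", "semi_natural", "semi_natural", sn_category="medium"),
        LandCoverClass(141, "deciduous_mixed_forest", "semi_natural", "semi_natural", sn_category="high"),
        LandCoverClass(142, "evergreen_forest", "semi_natural", "semi_natural", sn_category="low"),
        LandCoverClass(152, "shrubland", "semi_natural", "semi_natural", sn_category="medium"),
        LandCoverClass(176, "pasture", "semi_natural", "semi_natural", sn_category="medium"),
        LandCoverClass(190, "woody_wetland", "semi_natural", "semi_natural", sn_category="medium"),
        LandCoverClass(195, "herbaceous_wetland", "semi_natural", "semi_natural", sn_category="high"),
    ]
    excluded = [
        LandCoverClass(111, "open_water", "excluded", "excluded"),
        LandCoverClass(122, "developed", "excluded", "excluded"),
        LandCoverClass(131, "barren", "excluded", "excluded"),
        LandCoverClass(24, "winter_wheat", "excluded", "excluded"),  # non-bee crop
    ]
    return {c.code: c for c in crops + semi + excluded}


@dataclass
class LandCoverGrid:
    """A 30-m land-cover raster with the colony location and central field mask."""

    codes: np.ndarray
    colony_rc: tuple[int, int]
    central_mask: np.ndarray | None = None
    pixel_size_m: float = PIXEL_SIZE_M

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValueError("grid must be 2-D")
        r, c = self.colony_rc
        if not (0 <= r < self.codes.shape[0] and 0 <= c < self.codes.shape[1]):
            raise ValueError("colony pixel must lie inside the grid")
        if self.central_mask is not None:
            self.central_mask = np.asarray(self.central_mask, dtype=bool)
            if self.central_mask.shape != self.codes.shape:
                raise ValueError("central mask shape must match the grid")


@dataclass
class Patch:
    """One foraging resource unit.

    ``distance_m`` is the patch-centroid-to-colony distance used for trip
    times and reporting.  ``pixel_distances_m`` (when built from a grid)
    records where the patch's area actually lies, so that the foraging
    distance discount of a large or wrap-around patch reflects its true
    spatial extent rather than a possibly unrepresentative centroid.
    """

    id: int
    code: int
    name: str
    role: str
    category: str
    attractiveness: float
    area_m2: float
    distance_m: float
    is_central: bool = False
    pixel_distances_m: np.ndarray | None = field(default=None, repr=False)


def _pixel_centers_m(shape: tuple[int, int], pixel: float) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * pixel,
        (np.arange(shape[1]) + 0.5) * pixel,
        indexing="ij",
    )
    return rr, cc


def _distance_from_colony(grid: LandCoverGrid) -> np.ndarray:
    rr, cc = _pixel_centers_m(grid.codes.shape, grid.pixel_size_m)
    r0 = (grid.colony_rc[0] + 0.5) * grid.pixel_size_m
    c0 = (grid.colony_rc[1] + 0.5) * grid.pixel_size_m
    return np.hypot(rr - r0, cc - c0)


def build_patches(
    grid: LandCoverGrid,
    class_table: dict[int, LandCoverClass] | None = None,
    radius_m: float = 1500.0,
    min_area_m2: float = 10_000.0,
    connectivity: int = 4,
) -> list[Patch]:
    """Merge same-code adjacent pixels within the radius into patches.

    The central field mask always becomes its own patch at distance 0
    (regardless of adjacent same-code pixels) and is exempt from the
    minimum-area filter.  Excluded classes are dropped; an unknown code
    raises.  Distances run from the patch centroid to the colony pixel
    centre; pixel membership in the radius is decided by pixel centre.
    """
    classes = class_table or default_class_table()
    codes = grid.codes
    unknown = sorted(set(np.unique(codes)) - set(classes))
    if unknown:
        raise ValueError(f"grid contains codes missing from the class table: {unknown}")
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    else:
        raise ValueError("connectivity must be 4 or 8")

    dist = _distance_from_colony(grid)
    inside = dist <= radius_m
    central = grid.central_mask if grid.central_mask is not None else np.zeros_like(inside)

    patches: list[Patch] = []
    next_id = 0
    if central.any():
        code = int(codes[central][0])
        cdef = classes[code]
        patches.append(Patch(
            id=next_id, code=code, name=cdef.name, role=cdef.role,
            category=cdef.category, attractiveness=cdef.attractiveness,
            area_m2=float(central.sum()) * PIXEL_AREA_M2, distance_m=0.0,
            is_central=True, pixel_distances_m=dist[central].copy(),
        ))
        next_id += 1

    rr, cc = _pixel_centers_m(codes.shape, grid.pixel_size_m)
    r0 = (grid.colony_rc[0] + 0.5) * grid.pixel_size_m
    c0 = (grid.colony_rc[1] + 0.5) * grid.pixel_size_m
    for code in np.unique(codes):
        cdef = classes[int(code)]
        if cdef.role == "excluded":
            continue
        mask = (codes == code) & inside & ~central
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=structure)
        for lbl in range(1, n + 1):
            sel = labels == lbl
            npix = int(sel.sum())
            area = npix * PIXEL_AREA_M2
            if area < min_area_m2:
                continue
            dy = rr[sel].mean() - r0
            dx = cc[sel].mean() - c0
            patches.append(Patch(
                id=next_id, code=int(code), name=cdef.name, role=cdef.role,
                category=cdef.category, attractiveness=cdef.attractiveness,
                area_m2=area, distance_m=float(math.hypot(dy, dx)),
                pixel_distances_m=dist[sel].copy(),
            ))
            next_id += 1
    return patches


def resource_calendar(
    patch: Patch, class_table: dict[int, LandCoverClass] | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Daily (nectar L, pollen g) availability for days 1..365 of one patch.

    Returns ``(nectar_l, pollen_g, sugar_g_ml)`` with arrays indexed by
    day-of-year minus one.  Crop production is per-flower amounts times
    flower density and patch area on flowering days; semi-natural
    production is the monthly category level times area.
    """
    classes = class_table or default_class_table()
    cdef = classes[patch.code]
    nectar = np.zeros(365)
    pollen = np.zeros(365)
    if cdef.role == "crop":
        days = slice(cdef.flower_start - 1, cdef.flower_end)
        per_m2_nectar_ul = cdef.nectar_ul_per_flower * cdef.flower_density_m2
        per_m2_pollen_mg = cdef.pollen_mg_per_flower * cdef.flower_density_m2
        if not cdef.pollen_only:
            nectar[days] = per_m2_nectar_ul * patch.area_m2 * 1e-6  # uL -> L
        pollen[days] = per_m2_pollen_mg * patch.area_m2 * 1e-3  # mg -> g
        return nectar, pollen, cdef.sugar_g_ml
    if cdef.role == "semi_natural":
        factor = _SN_CATEGORY_FACTOR[cdef.sn_category]
        for day in range(1, 366):
            month = day_to_month(day)
            n_ul, p_mg = _SN_MONTHLY[month - 1]
            nectar[day - 1] = n_ul * factor * patch.area_m2 * 1e-6
            pollen[day - 1] = p_mg * factor * patch.area_m2 * 1e-3
        return nectar, pollen, _SN_SUGAR_G_ML
    raise ValueError(f"no resource calendar for excluded class {cdef.name}")


@dataclass
class PatchDayView:
    """Per-patch arrays for one simulation day (input to trip allocation)."""

    ids: np.ndarray
    distance_m: np.ndarray
    attractiveness: np.ndarray
    gather_pollen_s: np.ndarray
    gather_nectar_s: np.ndarray
    pollen_avail_g: np.ndarray
    nectar_avail_l: np.ndarray
    sugar_g_per_ml: np.ndarray
    residue_ng_g: np.ndarray
    #: optional pixel-area-mean distance discount (see Landscape.discounts)
    discount: np.ndarray | None = None


class Landscape:
    """Patches plus their daily resource calendars and the residue schedule."""

    def __init__(
        self,
        patches: list[Patch],
        class_table: dict[int, LandCoverClass] | None = None,
        tasseling: tuple[int, int] = TASSELING_WINDOW,
    ) -> None:
        self.patches = patches
        self.class_table = class_table or default_class_table()
        self.tasseling = tasseling
        n = len(patches)
        self.ids = np.array([p.id for p in patches], dtype=int)
        self.distance_m = np.array([p.distance_m for p in patches])
        self.attractiveness = np.array([p.attractiveness for p in patches])
        self.roles = np.array([p.role for p in patches])
        self.nectar_l = np.zeros((n, 365))
        self.pollen_g = np.zeros((n, 365))
        self.sugar = np.zeros(n)
        for i, p in enumerate(patches):
            self.nectar_l[i], self.pollen_g[i], self.sugar[i] = resource_calendar(
                p, self.class_table
            )
        central = [i for i, p in enumerate(patches) if p.is_central]
        self.central_index = central[0] if central else None
        self.gather_pollen_s = np.full(n, 600.0)
        self.gather_nectar_s = np.full(n, 1200.0)
        self._discount_cache: dict[tuple[float, float], np.ndarray] = {}

    def discounts(self, d_half_m: float, exponent: float) -> np.ndarray:
        """Per-patch foraging distance discount ``(1 + d/d_half)**-k``.

        Averaged over the patch's pixels where pixel distances are known
        (so a large patch counts each part of its area at its actual
        distance); falls back to the centroid distance otherwise.
        """
        key = (d_half_m, exponent)
        if key not in self._discount_cache:
            out = np.empty(len(self.patches))
            for i, p in enumerate(self.patches):
                d = (
                    p.pixel_distances_m
                    if p.pixel_distances_m is not None
                    else np.array([p.distance_m])
                )
                out[i] = float(np.mean((1.0 + d / d_half_m) ** -exponent))
            self._discount_cache[key] = out
        return self._discount_cache[key]

    def set_gathering_times(
        self,
        crop_pollen_s: float = 600.0,
        crop_nectar_s: float = 1200.0,
        semi_natural_pollen_s: float = 600.0,
        semi_natural_nectar_s: float = 1200.0,
    ) -> None:
        sn = self.roles == "semi_natural"
        self.gather_pollen_s = np.where(sn, semi_natural_pollen_s, crop_pollen_s)
        self.gather_nectar_s = np.where(sn, semi_natural_nectar_s, crop_nectar_s)

    def residue_ng_g(self, day_of_year: int, level: float) -> np.ndarray:
        """Residue concentration per patch: the central field carries the
        configured level, constant over the tasseling window; all other
        patches and days are clean."""
        conc = np.zeros(len(self.patches))
        if (
            self.central_index is not None
            and self.tasseling[0] <= day_of_year <= self.tasseling[1]
        ):
            conc[self.central_index] = level
        return conc

    def day_view(
        self,
        day_of_year: int,
        residue_level: float = 0.0,
        discount: np.ndarray | None = None,
    ) -> PatchDayView:
        if not 1 <= day_of_year <= 365:
            raise ValueError("day_of_year must be in [1, 365]")
        return PatchDayView(
            discount=discount,
            ids=self.ids,
            distance_m=self.distance_m,
            attractiveness=self.attractiveness,
            gather_pollen_s=self.gather_pollen_s,
            gather_nectar_s=self.gather_nectar_s,
            pollen_avail_g=self.pollen_g[:, day_of_year - 1].copy(),
            nectar_avail_l=self.nectar_l[:, day_of_year - 1].copy(),
            sugar_g_per_ml=self.sugar,
            residue_ng_g=self.residue_ng_g(day_of_year, residue_level),
        )


def build_landscape(
    grid: LandCoverGrid,
    class_table: dict[int, LandCoverClass] | None = None,
    radius_m: float = 1500.0,
    min_area_m2: float = 10_000.0,
    connectivity: int = 4,
) -> Landscape:
    patches = build_patches(grid, class_table, radius_m, min_area_m2, connectivity)
    return Landscape(patches, class_table)


def composition_metrics(
    grid: LandCoverGrid,
    class_table: dict[int, LandCoverClass] | None = None,
    radius_m: float = 1500.0,
) -> dict[str, float]:
    """Percent of the 1.5-km circle in each land-cover category.

    The denominator is the number of pixels whose centre lies inside the
    circle (a pixelated stand-in for the full circle area), so excluded
    covers count toward the denominator and the categories sum to <= 100%.
    """
    classes = class_table or default_class_table()
    dist = _distance_from_colony(grid)
    inside = dist <= radius_m
    total = float(inside.sum())
    out = {"semi_natural": 0.0, "other_crop": 0.0, "alfalfa_buckwheat": 0.0}
    for code in np.unique(grid.codes[inside]):
        cdef = classes.get(int(code))
        if cdef is None:
            raise ValueError(f"code {code} missing from class table")
        if cdef.category in out:
            npix = float(((grid.codes == code) & inside).sum())
            out[cdef.category] += 100.0 * npix / total
    return out


# ---------------------------------------------------------------------------
# Synthetic landscape generation
# ---------------------------------------------------------------------------

def _mosaic_fill(
    rng: np.random.Generator,
    inside: np.ndarray,
    quotas: dict[int, int],
    fixed: np.ndarray,
    ring_width_px: int = 7,
) -> np.ndarray:
    """Seeded ring-mosaic fill of the ``inside`` pixels.

    The circle around the hive is cut into annuli; within each annulus
    the free pixels, ordered by angle with a random rotation and class
    order, are split into contiguous arcs sized proportionally to each
    class's remaining quota.  Arcs are field-sized clustered regions,
    and every class receives the same radial profile in proportion to
    its cover fraction, so near-hive resource supply scales with
    landscape composition rather than with where a random growth seed
    happened to land.  ``fixed`` holds pre-assigned codes (the central
    field) as >0.
    """
    shape = inside.shape
    assigned = np.where(fixed > 0, fixed, 0).astype(int)
    free = inside & (assigned == 0)
    centre = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    cells = np.argwhere(free)
    rel = cells - centre
    radii = np.hypot(rel[:, 0], rel[:, 1])
    angles = np.arctan2(rel[:, 0], rel[:, 1])

    codes = sorted(quotas)
    total_quota = sum(quotas.values())
    n_free = len(cells)
    remaining = {
        c: quotas[c] - int(((assigned == c) & inside).sum()) for c in codes
    }
    remaining = {c: max(0, v) for c, v in remaining.items()}
    scale = n_free / max(1, sum(remaining.values()))

    n_rings = max(1, int(math.ceil(radii.max() / ring_width_px))) if n_free else 0
    edges = np.linspace(0.0, radii.max() + 1e-9, n_rings + 1)
    for k in range(n_rings):
        sel = (radii >= edges[k]) & (radii < edges[k + 1])
        ring_cells = cells[sel]
        if len(ring_cells) == 0:
            continue
        rot = rng.uniform(0, 2 * math.pi)
        order = np.argsort((angles[sel] + rot) % (2 * math.pi))
        ring_cells = ring_cells[order]
        live = [c for c in codes if remaining[c] > 0]
        if not live:
            live = codes[-1:]
        live = [live[i] for i in rng.permutation(len(live))]
        weights = np.array([max(remaining[c], 0) for c in live], dtype=float)
        if weights.sum() <= 0:
            weights[:] = 1.0
        shares = weights / weights.sum() * len(ring_cells)
        counts = np.floor(shares).astype(int)
        for i in np.argsort(shares - counts)[::-1][: len(ring_cells) - counts.sum()]:
            counts[i] += 1
        pos = 0
        for code, cnt in zip(live, counts):
            for r, c in ring_cells[pos : pos + cnt]:
                assigned[r, c] = code
            remaining[code] -= cnt
            pos += cnt
    return assigned


def synthesize_landscape(
    seed: int,
    fractions: dict[str, float],
    central_field_ha: float = 10.0,
    shape: tuple[int, int] = (101, 101),
    class_table: dict[int, LandCoverClass] | None = None,
    radius_m: float = 1500.0,
    tolerance_pct: float = 3.0,
    max_attempts: int = 6,
) -> LandCoverGrid:
    """Generate a clustered land-cover grid matching target category fractions.

    ``fractions`` maps ``semi_natural`` / ``other_crop`` /
    ``alfalfa_buckwheat`` to circle-area fractions (sum <= 1; the
    remainder becomes excluded developed land).  A contiguous central
    cornfield of the requested size, containing the colony pixel, is
    placed at the grid centre and counts toward the other-crop fraction.
    Deterministic for a given seed; raises if the measured composition
    misses the targets by more than ``tolerance_pct`` after a few
    attempts.
    """
    targets = {k: float(fractions.get(k, 0.0)) for k in
               ("semi_natural", "other_crop", "alfalfa_buckwheat")}
    if any(v < 0 for v in targets.values()) or sum(targets.values()) > 1.0 + 1e-9:
        raise ValueError("fractions must be >= 0 and sum to <= 1")
    classes = class_table or default_class_table()

    r0, c0 = shape[0] // 2, shape[1] // 2
    dist = np.hypot(
        *np.meshgrid(
            (np.arange(shape[0]) - r0) * PIXEL_SIZE_M,
            (np.arange(shape[1]) - c0) * PIXEL_SIZE_M,
            indexing="ij",
        )
    )
    inside = dist <= radius_m
    n_inside = int(inside.sum())

    # central cornfield: contiguous block of pixels nearest the colony
    n_central = max(1, round(central_field_ha * 10_000 / PIXEL_AREA_M2))
    order = np.argsort(dist, axis=None, kind="stable")
    central_mask = np.zeros(shape, dtype=bool)
    central_mask.flat[order[:n_central]] = True

    # split category targets across concrete classes
    splits = {
        "semi_natural": {176: 0.55, 141: 0.45},
        "other_crop": {1: 0.5, 5: 0.5},
        "alfalfa_buckwheat": {36: 1.0},
    }
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        quotas: dict[int, int] = {}
        for cat, frac in targets.items():
            if frac <= 0:
                continue
            for code, w in splits[cat].items():
                quotas[code] = round(frac * w * n_inside)
        # corn quota absorbs the pre-assigned central field
        if 1 in quotas:
            quotas[1] = max(quotas[1], n_central)
        # the remainder grows as developed/excluded land so that the
        # hole-filling pass cannot inflate the resource classes
        remainder = n_inside - sum(quotas.values())
        if remainder > 0:
            quotas[122] = remainder
        fixed = np.where(central_mask, 1, 0)
        assigned = _mosaic_fill(rng, inside, quotas, fixed)
        # everything else (incl. outside the circle) is developed/excluded
        codes = np.where(assigned > 0, assigned, 122)
        grid = LandCoverGrid(codes=codes, colony_rc=(r0, c0), central_mask=central_mask)
        comp = composition_metrics(grid, classes, radius_m)
        if all(
            abs(comp[cat] - 100.0 * frac) <= tolerance_pct
            for cat, frac in targets.items()
        ):
            return grid
    raise ValueError(
        f"could not reach target composition {targets} within "
        f"{tolerance_pct}% after {max_attempts} attempts; got {comp}"
    )


# ---------------------------------------------------------------------------
# Synthetic weather
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeatherParams:
    """Temperate-season weather generator settings (upper-Midwest defaults)."""

    latitude_deg: float = 44.0
    tmax_mean: float = 12.5
    tmax_amplitude: float = 16.0
    tmax_sd: float = 3.0
    warmest_day: int = 200
    wet_day_prob: float = 0.3


def day_length_hours(day_of_year: int, latitude_deg: float) -> float:
    """Astronomical day length from solar declination (hours)."""
    decl = math.radians(23.44) * math.sin(2 * math.pi * (day_of_year - 80) / 365.0)
    x = -math.tan(math.radians(latitude_deg)) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    return 24.0 * math.acos(x) / math.pi


def synthesize_weather(
    seed: int, params: WeatherParams | None = None
) -> list[WeatherDay]:
    """365 days of synthetic weather: sinusoidal tmax + seeded wet days."""
    p = params or WeatherParams()
    rng = np.random.default_rng(seed)
    days = np.arange(1, 366)
    tmax = (
        p.tmax_mean
        + p.tmax_amplitude * np.cos(2 * np.pi * (days - p.warmest_day) / 365.0)
        + rng.normal(0.0, p.tmax_sd, size=365)
    )
    wet = rng.random(365) < p.wet_day_prob
    amounts = np.where(wet, rng.gamma(2.0, 3.0, size=365), 0.0)
    return [
        WeatherDay(
            tmax=float(tmax[i]),
            precip=float(amounts[i]),
            day_length=day_length_hours(int(days[i]), p.latitude_deg),
        )
        for i in range(365)
    ]
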