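"""Weather-gated foraging: trip allocation across patches and load collection.

The dance-recruitment forager agents of the parent colony model are
replaced by a deterministic allocation: available forager-seconds are
split across patches in proportion to a utility weight

    attractiveness * min(daily availability, saturation)
        / trip_time / (1 + distance / d_half)**k

where ``trip_time = 2 * distance / speed + gathering_time + handling``.
The explicit distance discount (half-distance ``d_half``, exponent ``k``)
keeps a field adjacent to the hive strongly favoured over equally
rewarding patches further out, as recruitment does in the full agent
model, and the availability term saturates so that one vast crop patch
cannot absorb the entire foraging force by area alone.  Collection from
any patch is capped by its daily availability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeatherDay",
    "ForagingParams",
    "foraging_hours",
    "pollen_forager_share",
    "allocate_trips",
    "collect_loads",
]


@dataclass(frozen=True)
class WeatherDay:
    """One day of weather: max temperature (degC), precipitation (mm), day length (h)."""

    tmax: float
    precip: float
    day_length: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.day_length <= 24.0:
            raise ValueError("day_length must be in [0, 24]")
        if self.precip < 0:
            raise ValueError("precipitation must be >= 0")


@dataclass(frozen=True)
class ForagingParams:
    flight_speed_ms: float = 6.5
    nectar_load_ul: float = 50.0
    pollen_load_g: float = 0.015
    handling_s: float = 300.0
    #: target pollen store size, in days of colony demand, with a floor
    #: (colonies hoard a reserve of bee bread even when brood is scarce)
    #: and a cap (comb space for bee bread is limited)
    pollen_target_days: float = 7.0
    pollen_store_floor_g: float = 2000.0
    pollen_store_cap_g: float = 6000.0
    #: fresh collection tracks daily demand (x margin) so consumers eat
    #: recent pollen; the reserve refills at this fraction of its deficit
    pollen_demand_margin: float = 1.05
    pollen_refill_per_day: float = 0.2
    pollen_share_min: float = 0.0
    pollen_share_max: float = 0.8
    #: distance discount in the allocation weight: (1 + d/d_half)^-k
    distance_exponent: float = 3.0
    distance_half_m: float = 250.0
    #: availability saturation in the weight (g pollen / L nectar per day)
    pollen_weight_saturation_g: float = 50_000.0
    nectar_weight_saturation_l: float = 200.0
    #: mass of honey produced per mass of sugar
    honey_per_sugar: float = 1.0 / 0.8

    def __post_init__(self) -> None:
        for name in (
            "flight_speed_ms", "nectar_load_ul", "pollen_load_g", "handling_s",
            "pollen_target_days", "distance_exponent", "distance_half_m",
            "pollen_weight_saturation_g", "nectar_weight_saturation_l",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def foraging_hours(w: WeatherDay, t_threshold: float = 15.0) -> float:
    """Hours available for foraging on one day.

    Bees do not forage on days with any precipitation; on dry days the
    full day length is available whenever the maximum temperature reaches
    the threshold (default 15 degC).
    """
    if w.precip > 0:
        return 0.0
    if w.tmax >= t_threshold:
        return w.day_length
    return 0.0


def pollen_forager_share(
    store_mass_g: float,
    daily_demand_g: float,
    capacity_g: float,
    params: ForagingParams,
) -> float:
    """Fraction of forager effort devoted to pollen trips.

    Desired collection is the day's consumption (times a small margin)
    plus a fraction of the reserve deficit relative to a target store of
    ``pollen_target_days`` days of demand, bounded by the reserve floor
    and the comb-space cap.  Tracking consumption with fresh collection
    keeps the colony eating recent pollen, as it does in nature, instead
    of digging into the old pooled cohort whenever the reserve is full.
    ``capacity_g`` is the day's total collection capacity if every
    forager-second went to pollen.
    """
    target = min(
        max(params.pollen_target_days * daily_demand_g, params.pollen_store_floor_g),
        params.pollen_store_cap_g,
    )
    desired = (
        params.pollen_demand_margin * daily_demand_g
        + params.pollen_refill_per_day * max(0.0, target - store_mass_g)
    )
    desired = min(desired, max(0.0, params.pollen_store_cap_g - store_mass_g))
    if capacity_g <= 0 or desired <= 0:
        return params.pollen_share_min
    return float(
        np.clip(desired / capacity_g, params.pollen_share_min, params.pollen_share_max)
    )


def _trip_times(distance_m, gathering_s, params: ForagingParams) -> np.ndarray:
    return 2.0 * np.asarray(distance_m) / params.flight_speed_ms + np.asarray(
        gathering_s
    ) + params.handling_s


def _allocate(
    seconds: float,
    trip_time: np.ndarray,
    weights: np.ndarray,
    max_trips: np.ndarray,
) -> np.ndarray:
    """Split forager-seconds by weight into per-patch trips, capped.

    One redistribution pass sends seconds unused at capped patches to the
    remaining uncapped patches (documented single pass: tiny residual
    effort may go unused rather than looping to convergence).
    """
    trips = np.zeros_like(trip_time)
    if seconds <= 0 or weights.sum() <= 0:
        return trips
    share = weights / weights.sum()
    desired = share * seconds / trip_time
    trips = np.minimum(desired, max_trips)
    leftover = float(np.sum((desired - trips) * trip_time))
    open_mask = desired < max_trips
    if leftover > 0 and np.any(open_mask):
        w2 = np.where(open_mask, weights, 0.0)
        extra = (w2 / w2.sum()) * leftover / trip_time
        trips = np.minimum(trips + extra, max_trips)
    return trips


def allocate_trips(
    foragers: float,
    patches,
    hours: float,
    params: ForagingParams,
    pollen_need: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Allocate forager trips to patches for one day.

    Parameters
    ----------
    patches:
        Object exposing arrays ``distance_m``, ``gather_pollen_s``,
        ``gather_nectar_s``, ``attractiveness`` and per-day availability
        ``pollen_avail_g``, ``nectar_avail_l`` (see the landscape module's
        day view).
    pollen_need:
        Fraction of forager effort assigned to pollen trips (0..1).

    Returns
    -------
    (pollen_trips, nectar_trips) per patch, capped so that no patch's
    daily availability is over-drawn.
    """
    if hours < 0:
        raise ValueError("hours must be >= 0")
    n = len(patches.distance_m)
    if hours == 0 or foragers <= 0 or n == 0:
        return np.zeros(n), np.zeros(n)
    seconds = foragers * hours * 3600.0
    discount = getattr(patches, "discount", None)
    if discount is None:
        discount = (1.0 + np.asarray(patches.distance_m) / params.distance_half_m) ** (
            -params.distance_exponent
        )

    tt_p = _trip_times(patches.distance_m, patches.gather_pollen_s, params)
    cap_p = patches.pollen_avail_g / params.pollen_load_g
    w_p = (
        patches.attractiveness
        * np.minimum(patches.pollen_avail_g, params.pollen_weight_saturation_g)
        / tt_p
        * discount
    )
    w_p[patches.pollen_avail_g <= 0] = 0.0
    pollen_trips = _allocate(seconds * pollen_need, tt_p, w_p, cap_p)

    tt_n = _trip_times(patches.distance_m, patches.gather_nectar_s, params)
    cap_n = patches.nectar_avail_l / (params.nectar_load_ul * 1e-6)
    w_n = (
        patches.attractiveness
        * np.minimum(patches.nectar_avail_l, params.nectar_weight_saturation_l)
        / tt_n
        * discount
    )
    w_n[patches.nectar_avail_l <= 0] = 0.0
    nectar_trips = _allocate(seconds * (1.0 - pollen_need), tt_n, w_n, cap_n)
    return pollen_trips, nectar_trips


def collect_loads(
    pollen_trips: np.ndarray,
    nectar_trips: np.ndarray,
    patches,
    params: ForagingParams,
) -> tuple[float, list[tuple]]:
    """Convert trips into collected loads.

    Returns ``(sugar_kg, pollen_deposits)`` where each deposit is a tuple
    ``(patch_id, mass_g, concentration_ng_g)`` carrying the source
    patch's residue concentration for the day.  Pollen per patch is
    capped by the patch's remaining daily availability.
    """
    deposits = []
    for i, trips in enumerate(np.asarray(pollen_trips)):
        if trips <= 0:
            continue
        mass = min(trips * params.pollen_load_g, float(patches.pollen_avail_g[i]))
        if mass <= 0:
            continue
        deposits.append((patches.ids[i], mass, float(patches.residue_ng_g[i])))
    nectar_l = np.asarray(nectar_trips) * params.nectar_load_ul * 1e-6
    nectar_l = np.minimum(nectar_l, patches.nectar_avail_l)
    sugar_kg = float(np.sum(nectar_l * patches.sugar_g_per_ml))  # L * g/mL = kg
    return sugar_kg, deposits
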