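"""Personal-space capacity and unit congestion rate.

Following Hall's proxemics, each waiting person is allotted a disc of radius
``d_personal`` (personal distance, default 1.2 m), so a floor area ``A``
holds ``N_theoretical = A / (pi * d_personal**2)`` people before the crowd
becomes psychologically uncomfortable.  The unit congestion rate of an area
is the ratio of the observed occupancy to that theoretical capacity:

    R_c = N_actual / N_theoretical

R_c > 1 flags crowding; R_c well below 1 flags under-used floor space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .sampling import CountTable, OperatingHours

__all__ = [
    "round_half_up",
    "truncate",
    "AreaSpec",
    "CapacityResult",
    "CongestionObservation",
    "theoretical_capacity",
    "congestion_rate",
    "congestion_profile",
    "congestion_report",
    "DEFAULT_PERSONAL_DISTANCE",
]

DEFAULT_PERSONAL_DISTANCE = 1.2  # metres; Hall's "personal distance" (4 ft)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Report-time rounding, half away from zero (not banker's)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def truncate(value: float, decimals: int = 2) -> float:
    """Report-time truncation toward zero, the convention some planning
    tables use for capacity figures."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_DOWN))


@dataclass(frozen=True)
class AreaSpec:
    """Planning facts for one monitored area."""

    name: str
    area_m2: float
    seats: int = 0
    hours: OperatingHours | None = None

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError(f"area must be positive, got {self.area_m2}")
        if self.seats < 0:
            raise ValueError("seats must be non-negative")


@dataclass(frozen=True)
class CapacityResult:
    n_theoretical: float
    d_personal: float = DEFAULT_PERSONAL_DISTANCE


@dataclass(frozen=True)
class CongestionObservation:
    n_actual: float
    rate: float


def theoretical_capacity(
    area_m2: float, d_personal: float = DEFAULT_PERSONAL_DISTANCE
) -> CapacityResult:
    """People a floor area can hold at one personal-space disc per person."""
    if area_m2 <= 0:
        raise ValueError(f"area must be positive, got {area_m2}")
    if d_personal <= 0:
        raise ValueError(f"personal distance must be positive, got {d_personal}")
    return CapacityResult(area_m2 / (math.pi * d_personal**2), d_personal)


def congestion_rate(n_actual: float, capacity: CapacityResult) -> float:
    """Observed occupancy over theoretical capacity (dimensionless)."""
    if n_actual < 0:
        raise ValueError("actual occupancy cannot be negative")
    return n_actual / capacity.n_theoretical


def congestion_profile(
    table: CountTable,
    specs: list[AreaSpec],
    d_personal: float = DEFAULT_PERSONAL_DISTANCE,
    smooth_window: int = 1,
) -> dict[str, pd.DataFrame]:
    """Time-resolved congestion rates from a per-slot count table.

    Returns three views of the same R_c series:

    ``by_slot``
        areas x (day, slot) rates, optionally smoothed along time with a
        centred moving average of ``smooth_window`` slots.
    ``across_areas``
        for each slot instant, the rate in each area, ordered as given by
        ``specs`` (the patient-journey order) -- the fluctuation along the
        medical process at a fixed time.
    ``across_days``
        for each (area, slot-minute), the rate on each day -- day-over-day
        fluctuation at a fixed time.
    """
    if smooth_window < 1:
        raise ValueError("smoothing window must be >= 1")
    by_name = {s.name: s for s in specs}
    for area in table.areas:
        if area not in by_name:
            raise ValueError(f"no AreaSpec for table area {area!r}")

    caps = {
        name: theoretical_capacity(spec.area_m2, d_personal).n_theoretical
        for name, spec in by_name.items()
    }
    rates = table.cells.div(pd.Series(caps).reindex(table.cells.index), axis=0)
    if smooth_window > 1:
        rates = (
            rates.T.groupby(level="day", sort=False)
            .apply(
                lambda g: g.rolling(smooth_window, center=True, min_periods=1).mean()
            )
            .droplevel(0)
            .T
        )
    order = [s.name for s in specs if s.name in rates.index]
    across_areas = rates.loc[order].T
    across_days = rates.T.reset_index().pivot(index="slot", columns="day")
    return {
        "by_slot": rates,
        "across_areas": across_areas,
        "across_days": across_days,
    }


def congestion_report(
    table: CountTable,
    specs: list[AreaSpec],
    d_personal: float = DEFAULT_PERSONAL_DISTANCE,
) -> pd.DataFrame:
    """Per-area planning summary: capacity, mean occupancy, mean rate.

    Mean occupancy is taken over the area's operating-hour slots only (the
    table carries no closed-hour cells), i.e. weekly person-time divided by
    the number of sampled slots.
    """
    by_name = {s.name: s for s in specs}
    rows = []
    for area in table.areas:
        if area not in by_name:
            raise ValueError(f"no AreaSpec for table area {area!r}")
        spec = by_name[area]
        cap = theoretical_capacity(spec.area_m2, d_personal)
        cells = table.cells.loc[area].dropna()
        mean_actual = float(cells.mean())
        rows.append(
            {
                "area": area,
                "area_m2": spec.area_m2,
                "seats": spec.seats,
                "n_theoretical": cap.n_theoretical,
                "mean_n_actual": mean_actual,
                "mean_congestion_rate": congestion_rate(mean_actual, cap),
            }
        )
    return pd.DataFrame(rows).set_index("area")


def mean_rate_from_weekly_total(
    weekly_total: float,
    n_slots: int,
    area_m2: float,
    d_personal: float = DEFAULT_PERSONAL_DISTANCE,
) -> CongestionObservation:
    """Mean occupancy and rate from a weekly person-time sum over n slots."""
    if n_slots < 1:
        raise ValueError("slot count must be >= 1")
    mean_actual = weekly_total / n_slots
    cap = theoretical_capacity(area_m2, d_personal)
    return CongestionObservation(mean_actual, congestion_rate(mean_actual, cap))
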