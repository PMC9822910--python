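"""Published survey figures for the five-area emergency-department study.

These constants are the worked-example inputs shipped with the package: the
weekly per-area daily census, the architectural planning facts (floor area,
seats, operating hours), the mean observed occupancies, the 14-category
diagnosis tally and the record-keeping totals from the one-week tertiary-ED
survey the package's pipeline reproduces.  They are inputs to computations
(margins, capacities, congestion rates, percentages), never outputs.
"""

from __future__ import annotations

import pandas as pd

from .congestion import AreaSpec
from .sampling import HOURS_24H, HOURS_DAY_SHIFT, OperatingHours

__all__ = [
    "AREAS",
    "WEEKDAYS",
    "DAILY_COUNTS",
    "AREA_SPECS",
    "MEAN_WAITING_COUNTS",
    "DIAGNOSIS_CATEGORY_COUNTS",
    "AGE_BAND_COUNTS",
    "N_DIAGNOSES_COUNTS",
    "SEX_COUNTS",
    "TOTAL_RECORDS",
    "USABLE_RECORDS",
    "daily_counts_frame",
    "area_specs",
]

AREAS = [
    "Registered",
    "Pediatrics",
    "Internal medicine and Surgery",
    "Inspection",
    "Pharmacy",
]

WEEKDAYS = [
    "Monday",
    "Tuesday",
    "Wednesday",
    "Thursday",
    "Friday",
    "Saturday",
    "Sunday",
]

# day -> per-area daily person-time census (order follows AREAS)
DAILY_COUNTS: dict[str, list[int]] = {
    "Monday": [693, 1485, 963, 183, 75],
    "Tuesday": [599, 1584, 850, 136, 91],
    "Wednesday": [637, 1387, 902, 169, 89],
    "Thursday": [582, 1639, 869, 103, 78],
    "Friday": [650, 1541, 944, 114, 68],
    "Saturday": [682, 1335, 947, 225, 87],
    "Sunday": [647, 1465, 1037, 229, 78],
}

# name -> (floor area m^2, seats, operating hours)
_AREA_FACTS: dict[str, tuple[float, int, OperatingHours]] = {
    "Registered": (115.02, 12, HOURS_DAY_SHIFT),
    "Pediatrics": (67.14, 30, HOURS_24H),
    "Internal medicine and Surgery": (66.78, 16, HOURS_24H),
    "Inspection": (44.73, 1, HOURS_DAY_SHIFT),
    "Pharmacy": (110.24, 10, HOURS_DAY_SHIFT),
}

# name -> surveyed mean number of people waiting at one time
MEAN_WAITING_COUNTS: dict[str, float] = {
    "Registered": 30.54,
    "Pediatrics": 40.75,
    "Internal medicine and Surgery": 23.19,
    "Inspection": 7.84,
    "Pharmacy": 3.82,
}

# 14-category diagnosis tally over all recorded diagnoses
DIAGNOSIS_CATEGORY_COUNTS: dict[str, int] = {
    "Various infectious diseases": 151,
    "Oncology cancer": 2,
    "Endocrine system": 7,
    "Nervous system": 29,
    "Circulatory system": 32,
    "Respiratory system": 2036,
    "Digestive system": 396,
    "Immune system": 525,
    "Motor system": 21,
    "Genitourinary system": 64,
    "Obstetrics and congenital disorders": 10,
    "Trauma": 200,
    "Accident": 78,
    "Psychological problems and examination": 197,
}

# usable-record tallies per age band (half-open bands, years)
AGE_BAND_COUNTS: dict[str, int] = {
    "[0,1)": 288,
    "[1,3)": 721,
    "[3,6)": 1007,
    "[6,12)": 457,
    "[12,20)": 178,
    "[20,30)": 195,
    "[30,40)": 221,
    "[40,50)": 158,
    "[50,60)": 190,
    "[60,inf)": 260,
}

N_DIAGNOSES_COUNTS: dict[int, int] = {1: 2853, 2: 727, 3: 37}

SEX_COUNTS: dict[str, int] = {"Male": 1889, "Female": 1741}

TOTAL_RECORDS = 4717
USABLE_RECORDS = 3675


def daily_counts_frame() -> pd.DataFrame:
    """Areas x days DataFrame of the weekly daily census."""
    return pd.DataFrame(DAILY_COUNTS, index=AREAS)


def area_specs() -> list[AreaSpec]:
    """AreaSpec list in patient-journey order."""
    return [
        AreaSpec(name, area_m2=a, seats=s, hours=h)
        for name, (a, s, h) in _AREA_FACTS.items()
    ]
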