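"""Visit-record timing analysis: T1/T2 durations, grouping, group tests.

Each emergency visit record carries up to four milestone timestamps: the
earliest receipt (pickup), diagnosis, payment and drug-dispensing times.
Two durations are derived, both anchored at the receipt time:

    T2 = diagnosis time - receipt time          (diagnosis duration)
    T1 = dispense (or payment) - receipt time   (visit time after diagnosis)

Records missing a needed milestone, or yielding a negative duration, are
unusable and excluded.  Durations are then compared across factor groups
(sex, age band, number of diagnoses, disease category) with the classical
selection logic: two groups get a t-test; more groups get one-way ANOVA when
every group passes Shapiro-Wilk normality and Levene homogeneity at alpha
0.05, otherwise the Kruskal-Wallis H test.  Significance is declared at
P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VisitRecord",
    "VisitDurations",
    "GroupingScheme",
    "GroupTestResult",
    "compute_durations",
    "usable_fraction",
    "group_summary",
    "compare_groups",
    "influence_report",
    "records_to_frame",
    "read_records_csv",
    "write_records_csv",
]

ALPHA = 0.05


@dataclass(frozen=True)
class VisitRecord:
    """One emergency visit with milestone timestamps and covariates."""

    id: str
    sex: str
    age: float
    diagnoses: tuple[str, ...]
    t_receipt: datetime
    t_diagnosis: datetime | None = None
    t_payment: datetime | None = None
    t_dispense: datetime | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")


@dataclass(frozen=True)
class VisitDurations:
    """T1/T2 in minutes; ``usable`` is False when a milestone is missing or
    a duration comes out negative."""

    t1_minutes: float | None
    t2_minutes: float | None
    usable: bool

    @property
    def post_diagnosis_minutes(self) -> float | None:
        """T1 - T2: time strictly after the diagnosis milestone."""
        if self.t1_minutes is None or self.t2_minutes is None:
            return None
        return self.t1_minutes - self.t2_minutes


# Half-open age bands in years; 12 belongs to the adolescent band.
DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = (
    (0, 1),
    (1, 3),
    (3, 6),
    (6, 12),
    (12, 20),
    (20, 30),
    (30, 40),
    (40, 50),
    (50, 60),
    (60, float("inf")),
)


@dataclass(frozen=True)
class GroupingScheme:
    """Factor definitions for the influence analysis."""

    age_bands: tuple[tuple[float, float], ...] = DEFAULT_AGE_BANDS
    diagnosis_count_levels: tuple[int, ...] = (1, 2, 3)
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo = 0.0
        for a, b in self.age_bands:
            if a != lo or b <= a:
                raise ValueError("age bands must partition [0, inf) without gaps")
            lo = b
        if lo != float("inf"):
            raise ValueError("age bands must cover all non-negative ages")

    def age_band_label(self, age: float) -> str:
        for a, b in self.age_bands:
            if a <= age < b:
                return _band_label(a, b)
        raise ValueError(f"age {age} not covered by any band")

    def band_labels(self) -> list[str]:
        return [_band_label(a, b) for a, b in self.age_bands]


def _band_label(a: float, b: float) -> str:
    hi = "inf" if b == float("inf") else f"{b:g}"
    return f"[{a:g},{hi})"


def compute_durations(record: VisitRecord, prefer_dispense: bool = True) -> VisitDurations:
    """Derive T1/T2 (minutes) from a record's milestones.

    T1 uses the dispensing time when present, falling back to the payment
    time (``prefer_dispense=False`` swaps the preference).  A record is
    usable only if both durations exist and are non-negative.
    """
    t2 = _minutes(record.t_receipt, record.t_diagnosis)
    first, second = (
        (record.t_dispense, record.t_payment)
        if prefer_dispense
        else (record.t_payment, record.t_dispense)
    )
    end = first if first is not None else second
    t1 = _minutes(record.t_receipt, end)
    usable = t1 is not None and t2 is not None and t1 >= 0 and t2 >= 0
    return VisitDurations(t1_minutes=t1, t2_minutes=t2, usable=usable)


def _minutes(start: datetime, end: datetime | None) -> float | None:
    if end is None or pd.isna(end):
        return None
    return (pd.Timestamp(end) - pd.Timestamp(start)).total_seconds() / 60.0


def usable_fraction(records: list[VisitRecord]) -> tuple[int, float]:
    """(number of usable records, usable fraction of the total)."""
    if not records:
        raise ValueError("no records supplied")
    n = sum(compute_durations(r).usable for r in records)
    return n, n / len(records)


def group_summary(
    records: list[VisitRecord], scheme: GroupingScheme | None = None
) -> pd.DataFrame:
    """Per-level counts and percentages for each grouping factor.

    Percentages are taken within each factor's own denominator; for disease
    type that denominator is the total number of recorded diagnoses (a
    record with several diagnoses counts once per category).
    """
    scheme = scheme or GroupingScheme()
    if not records:
        raise ValueError("no records supplied")
    if scheme.categories:
        known = set(scheme.categories)
        for r in records:
            for d in r.diagnoses:
                if d not in known:
                    raise ValueError(f"unknown disease category {d!r}")
    rows = []

    def _add(factor: str, series: pd.Series) -> None:
        total = int(series.sum())
        for level, n in series.items():
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "count": int(n),
                    "percent": 100.0 * n / total,
                }
            )

    df = records_to_frame(records)
    _add("sex", df["sex"].value_counts())
    bands = df["age"].map(scheme.age_band_label)
    _add("age_band", bands.value_counts().reindex(scheme.band_labels()).dropna().astype(int))
    _add("n_diagnoses", df["n_diagnoses"].value_counts().sort_index())
    all_diag = pd.Series([d for r in records for d in r.diagnoses])
    _add("disease_type", all_diag.value_counts())
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def compare_groups(values, labels) -> GroupTestResult:
    """Compare a duration across factor groups with automatic test selection.

    Two groups: two-sample t-test.  More than two: one-way ANOVA when every
    group is Shapiro-Wilk-normal and Levene finds homogeneous variances
    (both at alpha 0.05), otherwise Kruskal-Wallis.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two observations")
    if len(groups) == 2:
        stat, p = stats.ttest_ind(groups[0], groups[1])
        return GroupTestResult("t-test", float(stat), float(p))
    normal = all(stats.shapiro(g).pvalue > ALPHA for g in groups)
    homoscedastic = stats.levene(*groups).pvalue > ALPHA
    if normal and homoscedastic:
        stat, p = stats.f_oneway(*groups)
        return GroupTestResult("anova", float(stat), float(p))
    stat, p = stats.kruskal(*groups)
    return GroupTestResult("kruskal-wallis", float(stat), float(p))


def influence_report(
    records: list[VisitRecord],
    scheme: GroupingScheme | None = None,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Factor-by-duration p-value table (T1 and T2 against each factor).

    Factor levels with fewer than ``min_group_size`` usable observations are
    dropped from that factor's test.  Disease type uses each record's primary
    (first-listed) diagnosis.
    """
    scheme = scheme or GroupingScheme()
    df = records_to_frame(records)
    df = df[df["usable"]]
    if df.empty:
        raise ValueError("no usable records")
    df = df.assign(
        age_band=df["age"].map(scheme.age_band_label),
        primary_diagnosis=[r.split(";")[0] for r in df["diagnoses"]],
    )
    factors = {
        "sex": "sex",
        "age_band": "age_band",
        "n_diagnoses": "n_diagnoses",
        "disease_type": "primary_diagnosis",
    }
    rows = []
    for factor, col in factors.items():
        keep = df.groupby(col)[col].transform("size") >= min_group_size
        sub = df[keep]
        if sub[col].nunique() < 2:
            continue
        for duration in ("t1_minutes", "t2_minutes"):
            res = compare_groups(sub[duration].to_numpy(), sub[col].to_numpy())
            rows.append(
                {
                    "factor": factor,
                    "duration": duration,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)


def records_to_frame(records: list[VisitRecord]) -> pd.DataFrame:
    """Flatten records (plus derived durations) into a DataFrame."""
    rows = []
    for r in records:
        d = compute_durations(r)
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "age": r.age,
                "n_diagnoses": len(r.diagnoses),
                "diagnoses": ";".join(r.diagnoses),
                "t_receipt": pd.Timestamp(r.t_receipt),
                "t_diagnosis": pd.Timestamp(r.t_diagnosis) if r.t_diagnosis else pd.NaT,
                "t_payment": pd.Timestamp(r.t_payment) if r.t_payment else pd.NaT,
                "t_dispense": pd.Timestamp(r.t_dispense) if r.t_dispense else pd.NaT,
                "t1_minutes": d.t1_minutes if d.t1_minutes is not None else np.nan,
                "t2_minutes": d.t2_minutes if d.t2_minutes is not None else np.nan,
                "usable": d.usable,
            }
        )
    return pd.DataFrame(rows)


def write_records_csv(records: list[VisitRecord], path) -> None:
    """Persist records as CSV with ISO-8601 timestamps; empty cell = missing."""
    df = records_to_frame(records)[
        [
            "id",
            "sex",
            "age",
            "diagnoses",
            "t_receipt",
            "t_diagnosis",
            "t_payment",
            "t_dispense",
        ]
    ]
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_records_csv(path) -> list[VisitRecord]:
    df = pd.read_csv(
        path, parse_dates=["t_receipt", "t_diagnosis", "t_payment", "t_dispense"]
    )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VisitRecord(
                id=str(row.id),
                sex=row.sex,
                age=float(row.age),
                diagnoses=tuple(str(row.diagnoses).split(";")),
                t_receipt=row.t_receipt.to_pydatetime(),
                t_diagnosis=None if pd.isna(row.t_diagnosis) else row.t_diagnosis.to_pydatetime(),
                t_payment=None if pd.isna(row.t_payment) else row.t_payment.to_pydatetime(),
                t_dispense=None if pd.isna(row.t_dispense) else row.t_dispense.to_pydatetime(),
            )
        )
    return records
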