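"""Synthetic waiting-room scenes, daily crowd profiles and visit records.

Everything downstream of the cameras is exercised on data generated here:
grayscale frames containing head-like elliptical blobs at known coordinates,
half-hourly expected-count profiles with morning/evening peaks, ten-frame
bundles emulating one-minute surveillance videos of a near-stationary crowd,
and emergency visit records with planted age / diagnosis-count effects on
the T1/T2 durations.  All randomness flows from one explicit seed per call;
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .reference import AGE_BAND_COUNTS, DIAGNOSIS_CATEGORY_COUNTS, N_DIAGNOSES_COUNTS
from .sampling import OperatingHours
from .visits import DEFAULT_AGE_BANDS, VisitRecord

__all__ = [
    "AnnotatedScene",
    "CrowdProfile",
    "SyntheticVisitConfig",
    "generate_scene",
    "generate_daily_profile",
    "generate_frame_bundle",
    "generate_visit_records",
    "default_profiles",
    "write_scene",
    "read_scene",
]


@dataclass
class AnnotatedScene:
    """Grayscale frame with exact per-head point annotations.

    ``heads`` holds 0-based (x, y) = (column, row) blob centres; ``count``
    always equals ``len(heads)`` and every point lies inside the image.
    """

    image: np.ndarray = field(repr=False)
    heads: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        for x, y in self.heads:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"head ({x}, {y}) outside {w}x{h} image")

    @property
    def count(self) -> int:
        return len(self.heads)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass(frozen=True)
class CrowdProfile:
    """Expected people count per half-hourly sampling slot for one area."""

    area_name: str
    slot_minutes: tuple[int, ...]
    expected_counts: tuple[float, ...]

    def __post_init__(self) -> None:
        diffs = np.diff(self.slot_minutes)
        if len(self.slot_minutes) != len(self.expected_counts):
            raise ValueError("slots and expected counts must align")
        if len(diffs) and not (diffs == 30).all():
            raise ValueError("slots must be strictly increasing on a 30-min grid")
        if any(c < 0 for c in self.expected_counts):
            raise ValueError("expected counts must be non-negative")


def generate_scene(
    n_heads: int,
    height: int = 96,
    width: int = 128,
    seed: int = 0,
    radius_range: tuple[float, float] = (4.0, 12.0),
) -> AnnotatedScene:
    """Render a textured background with ``n_heads`` elliptical head blobs.

    Blobs have randomized radii (default 4-12 px), orientation and darkness
    and may mildly overlap; the returned annotations are the exact integer
    blob centres.  Appearance realism is deliberately minimal — the counting
    task is what matters downstream.
    """
    if height < 64 or width < 64:
        raise ValueError(f"image must be at least 64x64, got {height}x{width}")
    if n_heads < 0:
        raise ValueError("n_heads must be non-negative")
    rng = np.random.default_rng(seed)

    # coarse smooth texture + fine grain, light background
    coarse = rng.normal(0.0, 0.06, (height // 8 + 1, width // 8 + 1))
    texture = np.kron(coarse, np.ones((8, 8)))[:height, :width]
    img = 0.75 + texture + rng.normal(0.0, 0.015, (height, width))

    yy, xx = np.mgrid[0:height, 0:width]
    heads: list[tuple[int, int]] = []
    for _ in range(n_heads):
        cx = int(rng.integers(0, width))
        cy = int(rng.integers(0, height))
        rx = rng.uniform(*radius_range)
        ry = rng.uniform(*radius_range)
        theta = rng.uniform(0, np.pi)
        dark = rng.uniform(0.05, 0.45)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        img[mask] = dark + 0.05 * texture[mask]
        heads.append((cx, cy))

    return AnnotatedScene(image=np.clip(img, 0.0, 1.0).astype(np.float32), heads=heads)


def generate_daily_profile(
    area_name: str,
    hours: OperatingHours | str,
    peaks: list[tuple[str | int, float, float]] = (),
    base: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> CrowdProfile:
    """Half-hourly expected counts: base + Gaussian bumps, clipped at zero.

    Each peak is (time, amplitude, width-minutes); time is "HH:MM" or minutes
    since midnight and must fall inside the operating hours.  A 24-h area
    yields 48 slots; an 8:00-18:00 area yields 21 (inclusive grid).
    Optional seeded noise (``noise_sd``) perturbs slots before clipping.
    """
    if isinstance(hours, str):
        hours = OperatingHours.parse(hours)
    slots = np.asarray(hours.slot_minutes(), dtype=float)
    lo, hi = (0.0, 24 * 60.0) if hours.all_day else (hours.open_minute, hours.close_minute)
    expected = np.full(slots.shape, float(base))
    for when, amp, width in peaks:
        t0 = _peak_minutes(when)
        if not (lo <= t0 <= hi):
            raise ValueError(f"peak at minute {t0} outside operating hours")
        expected += amp * np.exp(-((slots - t0) ** 2) / (2.0 * width**2))
    if noise_sd > 0:
        expected += np.random.default_rng(seed).normal(0.0, noise_sd, slots.shape)
    expected = np.clip(expected, 0.0, None)
    return CrowdProfile(
        area_name=area_name,
        slot_minutes=tuple(int(s) for s in slots),
        expected_counts=tuple(float(c) for c in expected),
    )


def _peak_minutes(when: str | int | float) -> float:
    if isinstance(when, str):
        h, m = when.split(":")
        return int(h) * 60.0 + int(m)
    return float(when)


def generate_frame_bundle(
    expected: float,
    seed: int = 0,
    n_frames: int = 10,
    height: int = 96,
    width: int = 128,
) -> list[AnnotatedScene]:
    """Ten frames emulating one slot's one-minute video.

    The slot's crowd size is one Poisson(expected) draw; individual frames
    jitter by at most +/-1 person around it (the waiting crowd is treated as
    stationary).  An empty slot yields empty frames.
    """
    if expected < 0:
        raise ValueError("expected count must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(expected))
    frames = []
    for i in range(n_frames):
        jitter = int(rng.integers(-1, 2)) if n >= 1 else 0
        frame_seed = int(rng.integers(0, 2**31 - 1))
        frames.append(generate_scene(n + jitter, height, width, seed=frame_seed))
    return frames


_DISEASE_PROBS = {
    k: v / sum(DIAGNOSIS_CATEGORY_COUNTS.values())
    for k, v in DIAGNOSIS_CATEGORY_COUNTS.items()
}
_NDIAG_PROBS = {
    k: v / sum(N_DIAGNOSES_COUNTS.values()) for k, v in N_DIAGNOSES_COUNTS.items()
}
_AGE_BAND_PROBS = tuple(
    v / sum(AGE_BAND_COUNTS.values()) for v in AGE_BAND_COUNTS.values()
)

# Duration model constants (minutes).  T2 ~ N(30, 10); the post-diagnosis
# gap ~ N(60, 20); effects are expressed in units of these SDs.
_T2_BASE, _T2_SD = 30.0, 10.0
_GAP_BASE, _GAP_SD = 60.0, 20.0
_AGE_REF_MEAN, _AGE_REF_SD = 18.0, 20.0  # fixed standardization constants


@dataclass(frozen=True)
class SyntheticVisitConfig:
    """Study conditions for the synthetic visit-record generator.

    Effect sizes are in SD units of the affected duration per SD of the
    covariate (ages standardized against fixed reference constants, so the
    generator is a pure function of the config).  Category, diagnosis-count
    and age-band frequencies default to the one-week ED survey tallies; the
    missing-milestone fraction defaults to the survey's 22.1% unusable rate,
    missing completely at random.
    """

    n_records: int = 1000
    effect_age_t2: float = 0.0
    effect_age_t1: float = 0.0
    effect_ndiag_t1: float = 0.0
    category_probs: tuple[float, ...] = tuple(_DISEASE_PROBS.values())
    categories: tuple[str, ...] = tuple(_DISEASE_PROBS.keys())
    ndiag_probs: tuple[float, ...] = tuple(_NDIAG_PROBS.values())
    missing_fraction: float = 0.221
    noise_scale: float = 1.0
    male_fraction: float = 0.5203
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError("disease-category probabilities must sum to 1")
        if abs(sum(self.ndiag_probs) - 1.0) > 1e-9:
            raise ValueError("diagnosis-count probabilities must sum to 1")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing fraction must lie in [0, 1)")
        if len(self.category_probs) != len(self.categories):
            raise ValueError("one probability per category required")


def generate_visit_records(config: SyntheticVisitConfig) -> list[VisitRecord]:
    """Seeded emergency visit records with planted T1/T2 effects.

    Ages follow the survey's band frequencies (uniform within band); each
    record draws 1-3 distinct diagnosis categories; T2 and the
    post-diagnosis gap are Gaussian in minutes with the configured effects
    added, truncated at 2 min.  A ``missing_fraction`` share of records
    loses, completely at random, either the diagnosis milestone or both the
    payment and dispensing milestones, making it unusable downstream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    base_day = datetime(2020, 10, 26)  # Monday anchoring a synthetic week

    band_idx = rng.choice(len(DEFAULT_AGE_BANDS), size=n, p=_AGE_BAND_PROBS)
    ages = np.empty(n)
    for i, bi in enumerate(band_idx):
        lo, hi = DEFAULT_AGE_BANDS[bi]
        ages[i] = rng.uniform(lo, min(hi, 95.0))
    z_age = (ages - _AGE_REF_MEAN) / _AGE_REF_SD

    sexes = np.where(rng.random(n) < config.male_fraction, "Male", "Female")
    ndiag = rng.choice((1, 2, 3), size=n, p=np.asarray(config.ndiag_probs))
    cat_p = np.asarray(config.category_probs)

    t2 = (
        _T2_BASE
        + config.effect_age_t2 * _T2_SD * z_age
        + rng.normal(0.0, _T2_SD * config.noise_scale, n)
    )
    gap = (
        _GAP_BASE
        + config.effect_age_t1 * _GAP_SD * z_age
        + config.effect_ndiag_t1 * _GAP_SD * (ndiag - 1)
        + rng.normal(0.0, _GAP_SD * config.noise_scale, n)
    )
    t2 = np.clip(t2, 2.0, None)
    gap = np.clip(gap, 2.0, None)
    t1 = t2 + gap

    day = rng.integers(0, 7, n)
    arrival_min = rng.uniform(8 * 60, 20 * 60, n)
    drop = rng.random(n) < config.missing_fraction
    drop_diag = rng.random(n) < 0.5  # which milestone(s) to blank when dropping

    records = []
    for i in range(n):
        receipt = base_day + timedelta(days=int(day[i]), minutes=float(arrival_min[i]))
        diagnosis = receipt + timedelta(minutes=float(t2[i]))
        dispense = receipt + timedelta(minutes=float(t1[i]))
        payment = receipt + timedelta(minutes=float(t2[i] + 0.6 * gap[i]))
        # independent draws keep each category's marginal frequency at its
        # configured probability (a record may repeat a category)
        cats = rng.choice(len(cat_p), size=int(ndiag[i]), replace=True, p=cat_p)
        diagnoses = tuple(config.categories[c] for c in cats)
        if drop[i]:
            if drop_diag[i]:
                diagnosis = None
            else:
                payment = dispense = None
        records.append(
            VisitRecord(
                id=f"V{i:05d}",
                sex=str(sexes[i]),
                age=float(round(ages[i], 1)),
                diagnoses=diagnoses,
                t_receipt=receipt,
                t_diagnosis=diagnosis,
                t_payment=payment,
                t_dispense=dispense,
            )
        )
    return records


def default_profiles(seed: int = 0) -> list[CrowdProfile]:
    """Five-area daily profiles emulating the surveyed ED's rhythm.

    Bounded-hour areas peak mid-morning and before closing; Pediatrics runs
    high all day with an 8:30-9:30 ramp.  Amplitudes keep slot counts in the
    0-60 range bracketing the surveyed per-slot averages.
    """
    return [
        generate_daily_profile(
            "Registered", "8:00-18:00",
            peaks=[("11:00", 25, 60), ("17:00", 15, 60)], base=12, seed=seed,
        ),
        generate_daily_profile(
            "Pediatrics", "24h",
            peaks=[("9:30", 20, 150), ("20:00", 12, 120)], base=22, seed=seed + 1,
        ),
        generate_daily_profile(
            "Internal medicine and Surgery", "24h",
            peaks=[("10:00", 10, 180), ("21:00", 8, 120)], base=14, seed=seed + 2,
        ),
        generate_daily_profile(
            "Inspection", "8:00-18:00",
            peaks=[("8:30", 8, 45), ("17:30", 9, 45)], base=3, seed=seed + 3,
        ),
        generate_daily_profile(
            "Pharmacy", "8:00-18:00",
            peaks=[("11:00", 3, 90), ("16:00", 3, 90)], base=2, seed=seed + 4,
        ),
    ]


def write_scene(scene: AnnotatedScene, png_path, annotation_path=None) -> None:
    """Write a scene as 8-bit grayscale PNG plus a sidecar annotation file.

    The sidecar is CSV (``x,y`` per row) or JSON (with image dimensions)
    depending on the extension; default is ``<png>.csv``.
    """
    png_path = Path(png_path)
    img = (np.clip(scene.image, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(img, mode="L").save(png_path)
    ann = Path(annotation_path) if annotation_path else png_path.with_suffix(".csv")
    if ann.suffix == ".json":
        h, w = scene.shape
        ann.write_text(
            json.dumps({"height": h, "width": w, "heads": [list(p) for p in scene.heads]})
        )
    else:
        pd.DataFrame(scene.heads, columns=["x", "y"]).to_csv(ann, index=False)


def read_scene(png_path, annotation_path=None) -> AnnotatedScene:
    png_path = Path(png_path)
    img = np.asarray(Image.open(png_path).convert("L"), dtype=np.float32) / 255.0
    ann = Path(annotation_path) if annotation_path else png_path.with_suffix(".csv")
    if ann.suffix == ".json":
        data = json.loads(ann.read_text())
        heads = [tuple(p) for p in data["heads"]]
    else:
        df = pd.read_csv(ann)
        heads = [(int(x), int(y)) for x, y in zip(df["x"], df["y"])]
    return AnnotatedScene(image=img, heads=heads)
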