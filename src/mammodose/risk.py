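"""Dose categorisation and lifetime effective risk of radiation-induced
breast cancer.

A woman's dose profile is summarised by the median of her 36 predicted
per-age visit doses (MGD_MSR, mGy) and mapped to a low/medium/high category
by tertile boundaries of the training cohort's MGD_MSR distribution
(defaults 3.413 and 4.346 mGy).  Risk is then projected at the category
level: each screening age contributes the category's median MGD at that age
times the age-specific lifetime attributable risk (LAR) of breast cancer
per mGy, and the lifetime effective risk (LER) of a regimen is the sum of
those per-visit terms,

    LER = sum over visit ages of  MGD(age) * LAR(age)

in cases per 100,000 women, for incidence or mortality and for a dose and
dose-rate effectiveness factor (DDREF) of 1, 1.5 or 2.  The LAR is a
population parameter; the per-category projection is deliberate, and an
individual-profile mode exists only as an exploratory output.

LAR(age) is a cubic in age fitted through the BEIR VII female-breast anchor
values (ages 40, 50, 60, 70, 80); DDREF scaling is the exact ratio
1 : 2/3 : 1/2 relative to DDREF 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dosimetry import DoseProfile
from .exposure import SCREENING_AGES

__all__ = [
    "CATEGORIES",
    "ENDPOINTS",
    "DDREF_LEVELS",
    "DEFAULT_BOUNDARIES",
    "DoseCategoryBoundaries",
    "CategoryMGDTable",
    "LARModel",
    "ScreeningRegimen",
    "RiskReport",
    "PerVisitRisk",
    "assign_category",
    "compute_tertile_boundaries",
    "compute_category_medians",
    "effective_risk",
    "lifetime_effective_risk",
    "build_regimen",
    "build_risk_report",
    "risk_to_percent",
    "REGIMEN_PRESETS",
]

CATEGORIES = ("low", "medium", "high")
ENDPOINTS = ("incidence", "mortality")
DDREF_LEVELS = (1.0, 1.5, 2.0)
LAR_AGE_RANGE = (40, 80)


@dataclass(frozen=True)
class DoseCategoryBoundaries:
    """Tertile boundaries (mGy) splitting MGD_MSR into low/medium/high."""

    low_upper_mGy: float
    medium_upper_mGy: float

    def __post_init__(self) -> None:
        if not 0 < self.low_upper_mGy < self.medium_upper_mGy:
            raise ValueError(
                "require 0 < low_upper_mGy < medium_upper_mGy, got "
                f"({self.low_upper_mGy}, {self.medium_upper_mGy})"
            )


#: Training-cohort tertile boundaries of the MGD_MSR distribution, mGy.
DEFAULT_BOUNDARIES = DoseCategoryBoundaries(3.413, 4.346)


def assign_category(
    mgd_msr: float, boundaries: DoseCategoryBoundaries = DEFAULT_BOUNDARIES
) -> str:
    """Dose category for an MGD_MSR: half-open bands [0,b1), [b1,b2), [b2,inf)."""
    if not mgd_msr > 0:
        raise ValueError(f"mgd_msr must be > 0, got {mgd_msr}")
    if mgd_msr < boundaries.low_upper_mGy:
        return "low"
    if mgd_msr < boundaries.medium_upper_mGy:
        return "medium"
    return "high"


def compute_tertile_boundaries(msr_values: Sequence[float]) -> DoseCategoryBoundaries:
    """Empirical 1/3 and 2/3 quantiles of a cohort's MGD_MSR values.

    Uses linear interpolation between order statistics; degenerate
    (coincident) tertiles are refused.
    """
    arr = np.asarray(msr_values, dtype=float)
    if arr.size < 3:
        raise ValueError(f"need at least 3 MGD_MSR values, got {arr.size}")
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3])
    return DoseCategoryBoundaries(float(q1), float(q2))


@dataclass(frozen=True)
class CategoryMGDTable:
    """Per-category median MGD at each screening age 40-75 (mGy)."""

    per_category: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        cats = tuple(sorted(self.per_category))
        if cats != tuple(sorted(CATEGORIES)):
            raise ValueError(f"table must cover exactly the categories {CATEGORIES}")
        for cat, values in self.per_category.items():
            if len(values) != len(SCREENING_AGES):
                raise ValueError(f"category {cat!r} must have 36 per-age values")
        object.__setattr__(
            self,
            "per_category",
            {k: tuple(float(v) for v in vs) for k, vs in self.per_category.items()},
        )

    def mgd(self, category: str, age: int) -> float:
        if category not in self.per_category:
            raise ValueError(f"unknown dose category {category!r}")
        if not SCREENING_AGES[0] <= age <= SCREENING_AGES[-1]:
            raise ValueError(f"age {age} outside the table range 40..75")
        return self.per_category[category][age - SCREENING_AGES[0]]


def compute_category_medians(profiles: Iterable[DoseProfile]) -> CategoryMGDTable:
    """Per-age median dose across the profiles of each category."""
    grouped: dict[str, list[tuple[float, ...]]] = {c: [] for c in CATEGORIES}
    for profile in profiles:
        if profile.category not in grouped:
            raise ValueError(f"profile with missing/unknown category {profile.category!r}")
        grouped[profile.category].append(profile.per_age_mgd)
    empty = [c for c in CATEGORIES if not grouped[c]]
    if empty:
        raise ValueError(f"no profiles in dose category: {', '.join(empty)}")
    return CategoryMGDTable(
        {c: tuple(np.median(np.asarray(rows), axis=0)) for c, rows in grouped.items()}
    )


@dataclass(frozen=True)
class LARModel:
    """Cubic LAR-vs-age models per endpoint and DDREF, with BEIR VII anchors.

    ``coefficients`` maps (endpoint, ddref) to (a, b, c, d) of
    LAR = a*A^3 + b*A^2 + c*A + d in cases per 100,000 per mGy; ``anchors``
    maps endpoint to {age: cases per 100,000 per 0.1 Gy at DDREF 1.5}.
    """

    coefficients: Mapping[tuple[str, float], tuple[float, float, float, float]]
    anchors: Mapping[str, Mapping[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ep in ENDPOINTS:
            for dd in DDREF_LEVELS:
                if (ep, dd) not in self.coefficients:
                    raise ValueError(f"missing LAR coefficients for ({ep}, DDREF {dd})")

    def lar(self, age: float, endpoint: str, ddref: float) -> float:
        """LAR at an exposure age, cases per 100,000 per mGy."""
        ddref = float(ddref)
        if endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
        if ddref not in DDREF_LEVELS:
            raise ValueError(f"DDREF must be one of {DDREF_LEVELS}, got {ddref}")
        if not LAR_AGE_RANGE[0] <= age <= LAR_AGE_RANGE[1]:
            raise ValueError(
                f"age {age} outside the supported LAR range {LAR_AGE_RANGE} "
                "(the cubic is not extrapolated)"
            )
        return float(np.polyval(self.coefficients[(endpoint, ddref)], age))

    __call__ = lar


def effective_risk(mgd_mGy: float, lar_per_mGy: float) -> float:
    """Single-visit effective risk: dose times LAR, cases per 100,000."""
    return mgd_mGy * lar_per_mGy


@dataclass(frozen=True)
class ScreeningRegimen:
    """An ordered set of screening visit ages within 40-75."""

    name: str
    visit_ages: tuple[int, ...]

    def __post_init__(self) -> None:
        ages = tuple(int(a) for a in self.visit_ages)
        if not ages:
            raise ValueError("regimen must have at least one visit age")
        if any(a < SCREENING_AGES[0] or a > SCREENING_AGES[-1] for a in ages):
            raise ValueError(f"regimen ages must lie within [40, 75], got {ages}")
        if tuple(sorted(set(ages))) != ages:
            raise ValueError("regimen ages must be strictly increasing and distinct")
        object.__setattr__(self, "visit_ages", ages)

    @property
    def n_visits(self) -> int:
        return len(self.visit_ages)


# National screening-programme presets.  The UK programme invites women
# triennially from age 50; seven invitations span ages 50-68.
REGIMEN_PRESETS: dict[str, tuple[int, ...]] = {
    "australia_full": tuple(range(40, 50)) + tuple(range(50, 75, 2)),
    "australia_biennial": tuple(range(50, 75, 2)),
    "uk": tuple(range(50, 69, 3)),
    "usa": tuple(range(45, 55)) + tuple(range(55, 76, 2)),
}


def build_regimen(
    spec: str | Sequence[int] | None = None,
    *,
    start_age: int | None = None,
    end_age: int | None = None,
    interval_years: int | None = None,
    name: str | None = None,
) -> ScreeningRegimen:
    """Build a regimen from a preset name, an explicit age list, or
    (start_age, end_age, interval_years)."""
    if isinstance(spec, str):
        if spec not in REGIMEN_PRESETS:
            raise ValueError(
                f"unknown regimen preset {spec!r}; available: {sorted(REGIMEN_PRESETS)}"
            )
        return ScreeningRegimen(spec, REGIMEN_PRESETS[spec])
    if spec is not None:
        return ScreeningRegimen(name or "custom", tuple(int(a) for a in spec))
    if start_age is None or end_age is None or interval_years is None:
        raise ValueError("provide a preset name, an age list, or start/end/interval")
    if interval_years < 1 or end_age < start_age:
        raise ValueError("require interval_years >= 1 and end_age >= start_age")
    ages = tuple(range(int(start_age), int(end_age) + 1, int(interval_years)))
    return ScreeningRegimen(name or f"{start_age}:{end_age}:{interval_years}", ages)


def lifetime_effective_risk(
    category: str,
    regimen: ScreeningRegimen,
    endpoint: str,
    ddref: float,
    table: CategoryMGDTable,
    model: LARModel,
) -> float:
    """LER for a category and regimen: sum of per-visit dose*LAR terms."""
    return float(
        sum(
            effective_risk(table.mgd(category, age), model.lar(age, endpoint, ddref))
            for age in regimen.visit_ages
        )
    )


def risk_to_percent(cases_per_100k: float) -> float:
    """Present a per-100,000 risk as a percentage (divide by 1000)."""
    if cases_per_100k < 0:
        raise ValueError("risk cannot be negative")
    return cases_per_100k / 1000.0


@dataclass(frozen=True)
class PerVisitRisk:
    age: int
    mgd_mGy: float
    lar_incidence: float
    lar_mortality: float
    risk_incidence: float
    risk_mortality: float


@dataclass(frozen=True)
class RiskReport:
    """Per-visit effective risks and their LER sum for one category/regimen/DDREF."""

    category: str
    regimen: ScreeningRegimen
    ddref: float
    per_visit: tuple[PerVisitRisk, ...]
    individual: bool = False  # True when built from one woman's own profile

    @property
    def ler_incidence(self) -> float:
        return float(sum(v.risk_incidence for v in self.per_visit))

    @property
    def ler_mortality(self) -> float:
        return float(sum(v.risk_mortality for v in self.per_visit))

    @property
    def percent_incidence(self) -> float:
        return risk_to_percent(self.ler_incidence)

    @property
    def percent_mortality(self) -> float:
        return risk_to_percent(self.ler_mortality)


def build_risk_report(
    category: str,
    regimen: ScreeningRegimen,
    ddref: float,
    table: CategoryMGDTable,
    model: LARModel,
    *,
    profile: DoseProfile | None = None,
) -> RiskReport:
    """Assemble the per-visit risk rows and LER for a regimen.

    With ``profile`` given, the woman's own per-age doses replace the
    category medians (exploratory: the LAR is a population parameter, so a
    category-level projection is the supported headline output).
    """
    rows = []
    for age in regimen.visit_ages:
        mgd = profile.dose_at(age) if profile is not None else table.mgd(category, age)
        li = model.lar(age, "incidence", ddref)
        lm = model.lar(age, "mortality", ddref)
        rows.append(
            PerVisitRisk(age, mgd, li, lm, effective_risk(mgd, li), effective_risk(mgd, lm))
        )
    return RiskReport(
        category=category,
        regimen=regimen,
        ddref=float(ddref),
        per_visit=tuple(rows),
        individual=profile is not None,
    )
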