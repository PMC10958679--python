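"""Acquisition-parameter prediction from compressed breast thickness.

Hologic Selenia Dimensions units select tube voltage (kVp) and the
target/filter (T/F) combination almost deterministically from the
compressed breast thickness (CBT): W/Rh below 70 mm, W/Ag from 70 mm, with
kVp stepping up within each T/F run.  That behaviour is represented as a
banded lookup table over integer CBT, either supplied from the published
table or re-derived from cohort frequency data with
:func:`derive_kvp_tf_lookup`.

:func:`build_exposure_plan` assembles the full per-age acquisition forecast
for one woman: her first-visit MBD, CBT and mAs pick one percentile curve
from each family, and those curves plus the kVp/T/F lookup predict every
acquisition parameter for ages 40-75.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .curves import (
    PercentileCurve,
    PercentileFamily,
    eval_curve,
    predict_series,
    select_percentile_curve,
)

__all__ = [
    "TARGET_FILTERS",
    "CBT_RANGE_MM",
    "SCREENING_AGES",
    "KvpTfLookup",
    "ExposurePlan",
    "PlanEntry",
    "lookup_kvp_tf",
    "predict_mas",
    "derive_kvp_tf_lookup",
    "build_exposure_plan",
    "LookupConfigurationError",
]

logger = logging.getLogger(__name__)

TARGET_FILTERS = ("W/Rh", "W/Ag")
CBT_RANGE_MM = (20, 110)
#: The 36 potential screening ages.
SCREENING_AGES: tuple[int, ...] = tuple(range(40, 76))

MIN_MAS = 1.0


class LookupConfigurationError(ValueError):
    """Raised when a kVp/T-F lookup table has gaps, overlaps or bad values."""


def _normalise_tf(value: str) -> str:
    v = value.strip().replace("\\", "/").upper()
    mapping = {"W/RH": "W/Rh", "W/AG": "W/Ag"}
    if v not in mapping:
        raise ValueError(f"unknown target/filter {value!r}; expected one of {TARGET_FILTERS}")
    return mapping[v]


@dataclass(frozen=True)
class KvpTfLookup:
    """Contiguous integer-CBT bins mapping to (kVp, target/filter)."""

    bins: tuple[tuple[int, int, int, str], ...]  # (cbt_low, cbt_high, kvp, tf)

    def __post_init__(self) -> None:
        if not self.bins:
            raise LookupConfigurationError("lookup table has no bins")
        ordered = tuple(sorted(self.bins))
        object.__setattr__(self, "bins", ordered)
        lo, hi = CBT_RANGE_MM
        expected = lo
        for low, high, kvp, tf in ordered:
            if low != expected:
                raise LookupConfigurationError(
                    f"lookup bins must be contiguous over [{lo},{hi}] mm; "
                    f"expected bin starting at {expected}, got {low}"
                )
            if high < low:
                raise LookupConfigurationError(f"bin ({low},{high}) is inverted")
            if tf not in TARGET_FILTERS:
                raise LookupConfigurationError(f"unknown target/filter {tf!r}")
            expected = high + 1
        if expected != hi + 1:
            raise LookupConfigurationError(f"lookup bins must end at {hi} mm, ended at {expected - 1}")

    def __call__(self, cbt_mm: float) -> tuple[int, str]:
        return lookup_kvp_tf(self, cbt_mm)


def lookup_kvp_tf(lookup: KvpTfLookup, cbt_mm: float) -> tuple[int, str]:
    """kVp and target/filter for a CBT, after rounding to integer mm.

    Fractional CBT rounds half-up to the nearest millimetre and is clamped
    to the 20-110 mm table range before the bin match.
    """
    if not np.isfinite(cbt_mm):
        raise ValueError(f"cbt_mm must be finite, got {cbt_mm}")
    cbt = int(math.floor(float(cbt_mm) + 0.5))  # round half up
    cbt = min(max(cbt, CBT_RANGE_MM[0]), CBT_RANGE_MM[1])
    for low, high, kvp, tf in lookup.bins:
        if low <= cbt <= high:
            return kvp, tf
    raise LookupConfigurationError(f"no bin covers CBT {cbt} mm")  # pragma: no cover


def predict_mas(
    family: PercentileFamily, curve: PercentileCurve, cbt_mm: float, *, min_mas: float = MIN_MAS
) -> float:
    """Evaluate the selected cubic mAs curve at a CBT, floored at ``min_mas``.

    The cubic fits can dip below zero outside the fitted CBT range; a small
    positive floor keeps the prediction physical.
    """
    return max(eval_curve(curve, cbt_mm), min_mas)


def derive_kvp_tf_lookup(
    records: Iterable[tuple[float, int, str]], *, min_bin_count: int = 1
) -> KvpTfLookup:
    """Recover the machine's kVp/T-F selection table from cohort records.

    For each integer CBT the modal (kVp, T/F) pair across records is taken
    (mode ties break toward lower kVp, then W/Rh), empty interior CBTs are
    filled from the nearest populated neighbour, and runs of identical modal
    pairs merge into bins covering the full 20-110 mm range.
    """
    lo, hi = CBT_RANGE_MM
    counters: dict[int, Counter] = {}
    for cbt_mm, kvp, tf in records:
        cbt = min(max(int(math.floor(float(cbt_mm) + 0.5)), lo), hi)
        counters.setdefault(cbt, Counter())[(int(kvp), _normalise_tf(tf))] += 1

    if not counters:
        raise ValueError("no records supplied")

    modal: dict[int, tuple[int, str]] = {}
    for cbt, counter in counters.items():
        total = sum(counter.values())
        if total < min_bin_count:
            continue
        best = min(
            counter.items(),
            key=lambda kv: (-kv[1], kv[0][0], TARGET_FILTERS.index(kv[0][1])),
        )
        modal[cbt] = best[0]

    if not modal:
        raise ValueError("no CBT bin reaches the minimum record count")

    populated = sorted(modal)
    pairs: list[tuple[int, str]] = []
    for cbt in range(lo, hi + 1):
        if cbt in modal:
            pairs.append(modal[cbt])
        else:
            nearest = min(populated, key=lambda p: (abs(p - cbt), p))
            logger.warning("CBT %d mm has no data; filling kVp/T-F from %d mm", cbt, nearest)
            pairs.append(modal[nearest])

    bins: list[tuple[int, int, int, str]] = []
    start = lo
    for cbt in range(lo + 1, hi + 1):
        if pairs[cbt - lo] != pairs[start - lo]:
            kvp, tf = pairs[start - lo]
            bins.append((start, cbt - 1, kvp, tf))
            start = cbt
    kvp, tf = pairs[start - lo]
    bins.append((start, hi, kvp, tf))
    return KvpTfLookup(tuple(bins))


@dataclass(frozen=True)
class PlanEntry:
    """Predicted (or, at the presenting age, observed) acquisition at one age."""

    age: int
    mbd_pct: float
    cbt_mm: float
    kvp: int
    mas: float
    target_filter: str


@dataclass(frozen=True)
class ExposurePlan:
    """Per-age acquisition forecast for one woman, ages 40-75.

    ``mbd_percentile``/``cbt_percentile``/``mas_percentile`` record which
    curves the first visit selected.
    """

    entries: tuple[PlanEntry, ...]
    mbd_percentile: int
    cbt_percentile: int
    mas_percentile: int
    presenting_age: int

    def __post_init__(self) -> None:
        ages = tuple(e.age for e in self.entries)
        if ages != SCREENING_AGES:
            raise ValueError("plan must contain exactly one entry per age 40..75")

    def __getitem__(self, age: int) -> PlanEntry:
        return self.entries[age - SCREENING_AGES[0]]


def build_exposure_plan(
    *,
    age: int,
    mbd_pct: float,
    cbt_mm: float,
    mas: float,
    mbd_family: PercentileFamily,
    cbt_family: PercentileFamily,
    mas_family: PercentileFamily,
    lookup: KvpTfLookup,
    observed_kvp: int | None = None,
    observed_tf: str | None = None,
) -> ExposurePlan:
    """Forecast acquisition parameters for every screening age from one visit.

    The observed first-visit (MBD, CBT, mAs) select one percentile curve in
    each family; each age 40-75 then gets predicted MBD and CBT from age,
    kVp/T-F from predicted CBT via the lookup, and mAs from predicted CBT
    via the selected mAs curve.  At the presenting age the observed values
    replace the predictions (dose at the actual visit uses actual
    acquisition data); a mismatch between observed and looked-up kVp/T-F is
    logged but the observed value wins.
    """
    for name, value in (("age", age), ("mbd_pct", mbd_pct), ("cbt_mm", cbt_mm), ("mas", mas)):
        if value is None or not np.isfinite(value):
            raise ValueError(f"missing or non-finite required input field: {name}")
    age = int(age)
    if not SCREENING_AGES[0] <= age <= SCREENING_AGES[-1]:
        raise ValueError(f"presenting age must be in [40, 75], got {age}")

    mbd_curve = select_percentile_curve(mbd_family, age, mbd_pct)
    cbt_curve = select_percentile_curve(cbt_family, age, cbt_mm)
    mas_curve = select_percentile_curve(mas_family, cbt_mm, mas)

    ages = np.asarray(SCREENING_AGES, dtype=float)
    mbd_series = predict_series(mbd_family, mbd_curve, ages)
    cbt_series = predict_series(cbt_family, cbt_curve, ages)

    entries: list[PlanEntry] = []
    for i, a in enumerate(SCREENING_AGES):
        if a == age:
            kvp_pred, tf_pred = lookup_kvp_tf(lookup, cbt_mm)
            kvp = int(observed_kvp) if observed_kvp is not None else kvp_pred
            tf = _normalise_tf(observed_tf) if observed_tf is not None else tf_pred
            if (kvp, tf) != (kvp_pred, tf_pred):
                logger.warning(
                    "observed kVp/T-F (%d, %s) differ from lookup (%d, %s) at CBT %.1f mm",
                    kvp, tf, kvp_pred, tf_pred, cbt_mm,
                )
            entries.append(PlanEntry(a, float(mbd_pct), float(cbt_mm), kvp, float(mas), tf))
        else:
            cbt_a = float(cbt_series[i])
            kvp, tf = lookup_kvp_tf(lookup, cbt_a)
            mas_a = predict_mas(mas_family, mas_curve, cbt_a)
            entries.append(PlanEntry(a, float(mbd_series[i]), cbt_a, kvp, mas_a, tf))

    return ExposurePlan(
        entries=tuple(entries),
        mbd_percentile=mbd_curve.percentile,
        cbt_percentile=cbt_curve.percentile,
        mas_percentile=mas_curve.percentile,
        presenting_age=age,
    )
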