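"""Mean glandular dose per exposure and the 36-age lifetime dose profile.

The mean glandular dose (MGD) of a mammographic exposure follows the
standard conversion-factor formulation

    MGD = K * g * c * s

where K is the incident air kerma at the breast surface and g, c, s are the
tabulated conversion factors: g converts kerma to glandular dose for a 50%
glandularity reference breast (a function of beam HVL and compressed breast
thickness), c corrects to the woman's actual glandularity, and s corrects
for the anode/filter spectrum.  K itself comes from the tube output model

    K = mAs * A * kVp**n / (SID - ISD - CBT)**2

with A and n calibrated from the unit's QA survey, SID the source-to-image
distance and ISD the image-receptor-to-support-plate distance (all mm
here; A must be calibrated for mm distances).

Factor tables are supplied by the user in the published grid format (or as
synthetic fixtures from :mod:`mammodose.synthetic`) and interpolated
multilinearly; queries outside a grid are a hard error, because silently
extrapolating dosimetric conversion factors is unsafe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exposure import SCREENING_AGES, TARGET_FILTERS, ExposurePlan

__all__ = [
    "QAParameters",
    "FactorTables",
    "DoseProfile",
    "incident_air_kerma",
    "estimate_hvl",
    "interpolate_factors",
    "compute_mgd",
    "aggregate_visit_dose",
    "predict_lifetime_doses",
    "FactorDomainError",
]


class FactorDomainError(ValueError):
    """A factor-table query fell outside the tabulated grid (no extrapolation)."""


@dataclass(frozen=True)
class QAParameters:
    """Tube-output and geometry constants from a unit's QA survey.

    Parameters
    ----------
    tube_output_coeff
        A in the kerma model, mGy * mAs^-1 * kVp^-n referenced to 1 mm
        (i.e. calibrated for mm distances in the inverse-square term).
    kvp_exponent
        n, the kVp power of the tube output.
    sid_mm, isd_mm
        Source-to-image and image-to-support-plate distances, mm.
    hvl_model
        Per target/filter ``(intercept_mm_al, slope_mm_al_per_kvp)`` of a
        linear beam-quality model HVL = intercept + slope * kVp.
    distance_units
        Must be ``"mm"``; declared explicitly so configs cannot silently
        mix units.
    """

    tube_output_coeff: float
    kvp_exponent: float
    sid_mm: float
    isd_mm: float
    hvl_model: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    distance_units: str = "mm"

    def __post_init__(self) -> None:
        if self.distance_units != "mm":
            raise ValueError(
                f"QA distances must be declared in mm, got {self.distance_units!r}"
            )
        if self.tube_output_coeff <= 0:
            raise ValueError("tube_output_coeff must be > 0")
        if self.kvp_exponent <= 0:
            raise ValueError("kvp_exponent must be > 0")
        if not self.sid_mm > self.isd_mm >= 0:
            raise ValueError("require sid_mm > isd_mm >= 0")
        object.__setattr__(
            self,
            "hvl_model",
            {k: (float(v[0]), float(v[1])) for k, v in dict(self.hvl_model).items()},
        )


class FactorTables:
    """g/c/s conversion-factor grids with multilinear interpolation.

    ``g_grid`` is tabulated over (HVL mm Al, CBT mm), ``c_grid`` over
    (HVL, CBT, glandularity %), and ``s`` is an exact per-target/filter
    scalar.
    """

    def __init__(
        self,
        *,
        g_hvl: Sequence[float],
        g_cbt: Sequence[float],
        g_values: np.ndarray,
        c_hvl: Sequence[float],
        c_cbt: Sequence[float],
        c_gland: Sequence[float],
        c_values: np.ndarray,
        s_values: Mapping[str, float],
    ) -> None:
        g_values = np.asarray(g_values, dtype=float)
        c_values = np.asarray(c_values, dtype=float)
        for name, axis in (("g hvl", g_hvl), ("g cbt", g_cbt), ("c hvl", c_hvl),
                           ("c cbt", c_cbt), ("c glandularity", c_gland)):
            a = np.asarray(axis, dtype=float)
            if a.ndim != 1 or a.size < 2 or not np.all(np.diff(a) > 0):
                raise ValueError(f"{name} axis must be strictly increasing with >= 2 nodes")
        if np.any(g_values <= 0) or np.any(c_values <= 0):
            raise ValueError("all g/c factor values must be > 0")
        missing = [tf for tf in TARGET_FILTERS if tf not in s_values]
        if missing:
            raise ValueError(f"s-factor missing for target/filter: {missing}")
        if any(v <= 0 for v in s_values.values()):
            raise ValueError("all s-factor values must be > 0")

        self.g_axes = (np.asarray(g_hvl, float), np.asarray(g_cbt, float))
        self.c_axes = (np.asarray(c_hvl, float), np.asarray(c_cbt, float),
                       np.asarray(c_gland, float))
        self.g_values = g_values
        self.c_values = c_values
        self.s_values = {k: float(v) for k, v in s_values.items()}
        self._g = RegularGridInterpolator(self.g_axes, g_values, bounds_error=True)
        self._c = RegularGridInterpolator(self.c_axes, c_values, bounds_error=True)

    def g(self, hvl: float, cbt_mm: float) -> float:
        try:
            return float(self._g([[hvl, cbt_mm]])[0])
        except ValueError as exc:
            raise FactorDomainError(
                f"g-factor query (hvl={hvl}, cbt={cbt_mm}) outside grid: {exc}"
            ) from None

    def c(self, hvl: float, cbt_mm: float, glandularity_pct: float) -> float:
        try:
            return float(self._c([[hvl, cbt_mm, glandularity_pct]])[0])
        except ValueError as exc:
            raise FactorDomainError(
                f"c-factor query (hvl={hvl}, cbt={cbt_mm}, "
                f"glandularity={glandularity_pct}) outside grid: {exc}"
            ) from None

    def s(self, target_filter: str) -> float:
        if target_filter not in self.s_values:
            raise FactorDomainError(f"no s-factor for target/filter {target_filter!r}")
        return self.s_values[target_filter]


@dataclass(frozen=True)
class DoseProfile:
    """The 36 per-age predicted visit doses for one woman, ages 40-75."""

    per_age_mgd: tuple[float, ...]
    category: str | None = None

    def __post_init__(self) -> None:
        if len(self.per_age_mgd) != len(SCREENING_AGES):
            raise ValueError("profile must carry exactly 36 per-age doses (ages 40..75)")
        if any(d <= 0 for d in self.per_age_mgd):
            raise ValueError("all per-age doses must be > 0")
        object.__setattr__(self, "per_age_mgd", tuple(float(d) for d in self.per_age_mgd))

    @property
    def ages(self) -> tuple[int, ...]:
        return SCREENING_AGES

    @property
    def mgd_msr(self) -> float:
        """Median MGD per screening round over the 36 ages."""
        return float(np.median(self.per_age_mgd))

    def dose_at(self, age: int) -> float:
        return self.per_age_mgd[age - SCREENING_AGES[0]]

    def with_category(self, category: str) -> "DoseProfile":
        return DoseProfile(self.per_age_mgd, category=category)


def incident_air_kerma(mas: float, kvp: float, qa: QAParameters, cbt_mm: float) -> float:
    """Incident air kerma (mGy) from the tube-output inverse-square model."""
    fsd = qa.sid_mm - qa.isd_mm - cbt_mm  # focus-to-skin distance, mm
    if fsd <= 0:
        raise ValueError(
            f"non-positive focus-to-skin distance: SID-ISD-CBT = {fsd:.1f} mm"
        )
    return mas * qa.tube_output_coeff * kvp ** qa.kvp_exponent / fsd ** 2


def estimate_hvl(kvp: float, target_filter: str, qa: QAParameters) -> float:
    """Beam HVL (mm Al) from the per-target/filter linear kVp model."""
    if target_filter not in qa.hvl_model:
        raise ValueError(f"QA parameters define no HVL model for {target_filter!r}")
    intercept, slope = qa.hvl_model[target_filter]
    return intercept + slope * kvp


def interpolate_factors(
    tables: FactorTables,
    hvl: float,
    cbt_mm: float,
    glandularity_pct: float,
    target_filter: str,
) -> tuple[float, float, float]:
    """(g, c, s) at a beam quality/thickness/glandularity query point."""
    return (
        tables.g(hvl, cbt_mm),
        tables.c(hvl, cbt_mm, glandularity_pct),
        tables.s(target_filter),
    )


def compute_mgd(k: float, g: float, c: float, s: float) -> float:
    """Mean glandular dose (mGy) as the product K * g * c * s."""
    for name, value in (("k", k), ("g", g), ("c", c), ("s", s)):
        if value <= 0:
            raise ValueError(f"{name} must be > 0, got {value}")
    return k * g * c * s


def aggregate_visit_dose(image_doses: Mapping[str, Sequence[float]]) -> float:
    """Per-visit breast dose from per-image doses keyed by laterality.

    Both breasts imaged: the two per-breast dose sums are averaged (the
    breasts jointly form one organ).  A single laterality: its sum is
    reported unaveraged, treating the woman as post-mastectomy.
    """
    sums = {lat: float(np.sum(doses)) for lat, doses in image_doses.items() if len(doses)}
    if not sums:
        raise ValueError("no image doses supplied")
    if len(sums) > 2:
        raise ValueError(f"unexpected lateralities: {sorted(sums)}")
    return float(np.mean(list(sums.values())))


def predict_lifetime_doses(
    plan: ExposurePlan,
    qa: QAParameters,
    tables: FactorTables,
    *,
    projections_per_breast: int = 2,
    bilateral: bool = True,
) -> DoseProfile:
    """Predicted visit dose at every screening age 40-75.

    Each age's planned acquisition gives HVL from kVp and target/filter,
    kerma from the tube-output model, interpolated g/c/s factors (with the
    predicted MBD as glandularity), a per-projection MGD, and finally the
    visit dose assuming ``projections_per_breast`` identical projections per
    imaged breast aggregated by :func:`aggregate_visit_dose`.
    """
    if projections_per_breast < 1:
        raise ValueError("projections_per_breast must be >= 1")
    doses: list[float] = []
    for entry in plan.entries:
        try:
            hvl = estimate_hvl(entry.kvp, entry.target_filter, qa)
            k = incident_air_kerma(entry.mas, entry.kvp, qa, entry.cbt_mm)
            g, c, s = interpolate_factors(
                tables, hvl, entry.cbt_mm, entry.mbd_pct, entry.target_filter
            )
            per_image = compute_mgd(k, g, c, s)
        except ValueError as exc:
            raise type(exc)(f"age {entry.age}: {exc}") from exc
        images = [per_image] * projections_per_breast
        image_doses = {"L": images, "R": images} if bilateral else {"L": images}
        doses.append(aggregate_visit_dose(image_doses))
    return DoseProfile(tuple(doses))
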