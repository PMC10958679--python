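"""Percentile growth curves for breast characteristics and exposure.

Screening programmes observe a woman once and must anticipate how her
mammographic breast density (MBD), compressed breast thickness (CBT) and
tube loading (mAs) will evolve over the 36 potential screening ages 40-75.
The model captures each quantity with a family of 20 percentile polynomial
curves (levels 1, 5, 10, ..., 95): MBD and CBT are quadratics in age, mAs a
cubic in CBT.  A woman's first-visit observation picks the percentile curve
whose value at her presenting age (or CBT) is closest to what was measured,
and that curve then predicts the quantity at every other age.

Families can be evaluated from the published coefficients (see
:mod:`mammodose.datasets`) or re-fitted from a cohort of visits with
:func:`fit_percentile_family`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PERCENTILE_LEVELS",
    "Quantity",
    "PercentileCurve",
    "PercentileFamily",
    "eval_curve",
    "select_percentile_curve",
    "predict_series",
    "fit_percentile_family",
    "FittingError",
]

logger = logging.getLogger(__name__)

#: The 20 percentile levels a family must cover.
PERCENTILE_LEVELS: tuple[int, ...] = (1,) + tuple(range(5, 100, 5))


class Quantity(str, Enum):
    """Which quantity a percentile family describes, and against what axis."""

    MBD_VS_AGE = "mbd_vs_age"
    CBT_VS_AGE = "cbt_vs_age"
    MAS_VS_CBT = "mas_vs_cbt"


#: Natural x-domain of each family (ages in years, CBT in mm).
QUANTITY_DOMAIN: dict[Quantity, tuple[float, float]] = {
    Quantity.MBD_VS_AGE: (40.0, 75.0),
    Quantity.CBT_VS_AGE: (40.0, 75.0),
    Quantity.MAS_VS_CBT: (20.0, 110.0),
}

#: Physical bounds applied to predictions (lower, upper); None = unbounded.
QUANTITY_BOUNDS: dict[Quantity, tuple[float | None, float | None]] = {
    Quantity.MBD_VS_AGE: (0.0, 100.0),
    Quantity.CBT_VS_AGE: (20.0, 110.0),
    Quantity.MAS_VS_CBT: (1.0, None),
}

#: Polynomial order per quantity.
QUANTITY_ORDER: dict[Quantity, int] = {
    Quantity.MBD_VS_AGE: 2,
    Quantity.CBT_VS_AGE: 2,
    Quantity.MAS_VS_CBT: 3,
}


class FittingError(ValueError):
    """Raised when a percentile family cannot be fitted from the data given."""


@dataclass(frozen=True)
class PercentileCurve:
    """A single percentile polynomial, coefficients highest degree first."""

    percentile: int
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.percentile not in PERCENTILE_LEVELS:
            raise ValueError(f"percentile must be one of {PERCENTILE_LEVELS}, got {self.percentile}")
        if len(self.coefficients) not in (3, 4):
            raise ValueError("coefficients must have length 3 (quadratic) or 4 (cubic)")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, x: float) -> float:
        return eval_curve(self, x)


@dataclass(frozen=True)
class PercentileFamily:
    """Twenty percentile curves of a common order for one quantity."""

    quantity: Quantity
    curves: dict[int, PercentileCurve] = field(repr=False)

    def __post_init__(self) -> None:
        levels = tuple(sorted(self.curves))
        if levels != PERCENTILE_LEVELS:
            raise ValueError(
                f"family must contain exactly the levels {PERCENTILE_LEVELS}, got {levels}"
            )
        orders = {c.order for c in self.curves.values()}
        if len(orders) != 1:
            raise ValueError(f"all curves in a family must share one order, got {orders}")
        expected = QUANTITY_ORDER[Quantity(self.quantity)]
        if orders != {expected}:
            raise ValueError(f"{self.quantity} curves must have order {expected}")

    @property
    def domain(self) -> tuple[float, float]:
        return QUANTITY_DOMAIN[Quantity(self.quantity)]

    @property
    def bounds(self) -> tuple[float | None, float | None]:
        return QUANTITY_BOUNDS[Quantity(self.quantity)]

    def __getitem__(self, percentile: int) -> PercentileCurve:
        return self.curves[percentile]

    def __iter__(self) -> Iterable[PercentileCurve]:
        return iter(self.curves[p] for p in PERCENTILE_LEVELS)


def eval_curve(curve: PercentileCurve, x: float) -> float:
    """Evaluate the percentile polynomial at ``x`` (no clipping)."""
    if not np.isfinite(x):
        raise ValueError(f"x must be finite, got {x}")
    return float(np.polyval(curve.coefficients, x))


def select_percentile_curve(
    family: PercentileFamily, x_at: float, observed: float
) -> PercentileCurve:
    """Pick the family curve closest to an observation at the presenting x.

    The selected curve is the one whose evaluated value at ``x_at`` has the
    minimum absolute difference from ``observed``.  Ties break toward the
    lower percentile (the conservative, lower-dose direction).  ``x_at`` is
    clamped to the family domain; observations outside the 1st-95th envelope
    simply select the nearest extreme curve.
    """
    if not family.curves:
        raise ValueError("empty percentile family")
    lo, hi = family.domain
    x = min(max(float(x_at), lo), hi)
    best: PercentileCurve | None = None
    best_diff = np.inf
    for level in PERCENTILE_LEVELS:  # ascending: strict < keeps the lower tie
        curve = family[level]
        diff = abs(eval_curve(curve, x) - observed)
        if diff < best_diff:
            best, best_diff = curve, diff
    assert best is not None
    return best


def predict_series(
    family: PercentileFamily, curve: PercentileCurve, xs: Sequence[float]
) -> np.ndarray:
    """Evaluate ``curve`` at each x and clip to the family's physical bounds."""
    xs = np.asarray(xs, dtype=float)
    if xs.size == 0:
        raise ValueError("xs must be non-empty")
    values = np.polyval(curve.coefficients, xs)
    lower, upper = family.bounds
    return np.clip(values, lower, upper)


def fit_percentile_family(
    samples: Iterable[tuple[float, float]],
    quantity: Quantity | str,
    *,
    percentiles: Sequence[int] = PERCENTILE_LEVELS,
    order: int | None = None,
    bin_width: float = 1.0,
    min_bin_count: int = 10,
) -> PercentileFamily:
    """Fit a percentile family from (x, y) cohort samples.

    Samples are grouped into ``bin_width``-wide x bins (1 year for age, 1 mm
    for CBT by default).  Within each sufficiently populated bin the
    empirical percentile of y is taken (linear interpolation of order
    statistics), and each percentile level's bin values are least-squares
    fitted with a polynomial of the family's order against the mean x of
    each bin (the bin's recorded age/thickness when inputs are integers).

    Raises
    ------
    FittingError
        If fewer than ``order + 1`` populated bins remain.
    """
    quantity = Quantity(quantity)
    if order is None:
        order = QUANTITY_ORDER[quantity]
    if tuple(sorted(percentiles)) != PERCENTILE_LEVELS:
        raise ValueError("fitting requires the full set of 20 percentile levels")

    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]

    bin_index = np.floor(x / bin_width).astype(int)
    centres: list[float] = []
    bin_percentiles: list[np.ndarray] = []
    for idx in np.unique(bin_index):
        mask = bin_index == idx
        if mask.sum() < min_bin_count:
            logger.warning(
                "dropping bin at x=%.1f with only %d samples (< %d)",
                idx * bin_width, int(mask.sum()), min_bin_count,
            )
            continue
        centres.append(float(x[mask].mean()))
        bin_percentiles.append(np.percentile(y[mask], percentiles))

    if len(centres) < order + 1:
        raise FittingError(
            f"need at least {order + 1} populated x bins to fit order-{order} "
            f"percentile curves, got {len(centres)}"
        )

    centres_arr = np.asarray(centres)
    matrix = np.vstack(bin_percentiles)  # bins x levels
    curves: dict[int, PercentileCurve] = {}
    for j, level in enumerate(percentiles):
        coeffs = np.polyfit(centres_arr, matrix[:, j], order)
        curves[int(level)] = PercentileCurve(int(level), tuple(coeffs))
    return PercentileFamily(quantity=quantity, curves=curves)
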