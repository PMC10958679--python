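"""Model/Results interface over the screening dose-and-risk pipeline.

``ScreeningDoseModel`` is built from a cohort of first-visit records (or a
tidy per-image DataFrame) and ``fit()`` estimates the trainable components
of the dose model: the three percentile polynomial families (MBD vs age,
CBT vs age, mAs vs CBT) and the kVp/target-filter selection table.  The
returned ``ScreeningDoseResults`` carries those estimates with fit
diagnostics, prints a ``summary()`` table, and exposes the downstream
prediction chain (exposure plan, dose profile, category, lifetime risk)
for new women.

``ScreeningDoseResults.from_published()`` loads the packaged published
coefficients instead of fitting, giving the pre-trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .curves import (
    PERCENTILE_LEVELS,
    PercentileFamily,
    Quantity,
    eval_curve,
    fit_percentile_family,
)
from .dosimetry import DoseProfile, FactorTables, QAParameters, predict_lifetime_doses
from .exposure import ExposurePlan, KvpTfLookup, build_exposure_plan, derive_kvp_tf_lookup
from .records import VisitRecord, VisitSummary, summarise_visit
from .risk import (
    DEFAULT_BOUNDARIES,
    DoseCategoryBoundaries,
    LARModel,
    CategoryMGDTable,
    RiskReport,
    ScreeningRegimen,
    assign_category,
    build_risk_report,
)

__all__ = ["ScreeningDoseModel", "ScreeningDoseResults"]


def _records_to_frame(records: Iterable[VisitRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for img in rec.images:
            rows.append(
                {"woman_id": rec.woman_id, "visit_id": rec.visit_id,
                 "age_years": rec.age_years, "mbd_pct": img.mbd_pct,
                 "cbt_mm": img.cbt_mm, "kvp": img.kvp, "mas": img.mas,
                 "target_filter": img.target_filter}
            )
    return pd.DataFrame(rows)


class ScreeningDoseModel:
    """Trainable screening dose model over a cohort of visit images.

    Parameters
    ----------
    data
        Tidy per-image DataFrame with columns ``age_years, mbd_pct, cbt_mm,
        kvp, mas, target_filter`` (one row per image).
    """

    REQUIRED_COLUMNS = ("age_years", "mbd_pct", "cbt_mm", "kvp", "mas", "target_filter")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"cohort data missing columns: {missing}")
        if len(data) == 0:
            raise ValueError("cohort data is empty")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[VisitRecord]) -> "ScreeningDoseModel":
        return cls(_records_to_frame(records))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "ScreeningDoseModel":
        return cls(data)

    def fit(
        self, *, min_bin_count: int = 10, age_bin_years: float = 1.0, cbt_bin_mm: float = 1.0
    ) -> "ScreeningDoseResults":
        """Fit the percentile families and derive the kVp/T-F lookup."""
        df = self.data
        mbd_family = fit_percentile_family(
            zip(df["age_years"], df["mbd_pct"]), Quantity.MBD_VS_AGE,
            bin_width=age_bin_years, min_bin_count=min_bin_count,
        )
        cbt_family = fit_percentile_family(
            zip(df["age_years"], df["cbt_mm"]), Quantity.CBT_VS_AGE,
            bin_width=age_bin_years, min_bin_count=min_bin_count,
        )
        mas_family = fit_percentile_family(
            zip(df["cbt_mm"], df["mas"]), Quantity.MAS_VS_CBT,
            bin_width=cbt_bin_mm, min_bin_count=min_bin_count,
        )
        lookup = derive_kvp_tf_lookup(
            zip(df["cbt_mm"], df["kvp"], df["target_filter"])
        )
        return ScreeningDoseResults(
            mbd_family=mbd_family, cbt_family=cbt_family, mas_family=mas_family,
            kvp_tf_lookup=lookup, model=self,
            n_images=len(df), n_women=df["woman_id"].nunique() if "woman_id" in df else None,
        )


@dataclass(frozen=True)
class ScreeningDoseResults:
    """Fitted (or published) components of the screening dose model."""

    mbd_family: PercentileFamily
    cbt_family: PercentileFamily
    mas_family: PercentileFamily
    kvp_tf_lookup: KvpTfLookup
    model: ScreeningDoseModel | None = None
    n_images: int | None = None
    n_women: int | None = None
    lar_model: LARModel = field(default_factory=datasets.load_lar_model)
    category_table: CategoryMGDTable = field(default_factory=datasets.load_category_median_mgd)
    boundaries: DoseCategoryBoundaries = DEFAULT_BOUNDARIES

    @classmethod
    def from_published(cls) -> "ScreeningDoseResults":
        """The pre-trained model from the packaged published coefficients."""
        return cls(
            mbd_family=datasets.load_percentile_family(Quantity.MBD_VS_AGE),
            cbt_family=datasets.load_percentile_family(Quantity.CBT_VS_AGE),
            mas_family=datasets.load_percentile_family(Quantity.MAS_VS_CBT),
            kvp_tf_lookup=datasets.load_kvp_tf_lookup(),
        )

    # -- prediction chain ---------------------------------------------------

    def predict_plan(self, summary: VisitSummary | VisitRecord) -> ExposurePlan:
        """Per-age acquisition forecast from a woman's first visit."""
        if isinstance(summary, VisitRecord):
            summary = summarise_visit(summary)
        return build_exposure_plan(
            age=summary.age_years, mbd_pct=summary.mbd_pct, cbt_mm=summary.cbt_mm,
            mas=summary.mas, mbd_family=self.mbd_family, cbt_family=self.cbt_family,
            mas_family=self.mas_family, lookup=self.kvp_tf_lookup,
            observed_kvp=summary.kvp, observed_tf=summary.target_filter,
        )

    def predict_profile(
        self,
        summary: VisitSummary | VisitRecord,
        qa: QAParameters,
        tables: FactorTables,
        *,
        projections_per_breast: int = 2,
    ) -> DoseProfile:
        """36-age dose profile with its assigned low/medium/high category."""
        plan = self.predict_plan(summary)
        profile = predict_lifetime_doses(
            plan, qa, tables, projections_per_breast=projections_per_breast
        )
        return profile.with_category(assign_category(profile.mgd_msr, self.boundaries))

    def predict_risk(
        self,
        category: str,
        regimen: ScreeningRegimen,
        ddref: float,
        *,
        profile: DoseProfile | None = None,
    ) -> RiskReport:
        """Per-visit effective risks and their LER for a regimen."""
        return build_risk_report(
            category, regimen, ddref, self.category_table, self.lar_model, profile=profile
        )

    # -- presentation -------------------------------------------------------

    def summary(self, ages: Sequence[int] = (40, 55, 70)) -> str:
        """Readable overview of the fitted families and selection table."""
        lines = ["Screening dose model", "=" * 60]
        if self.n_images is not None:
            src = f"fitted from {self.n_images} images"
            if self.n_women:
                src += f" ({self.n_women} women)"
        else:
            src = "published coefficients"
        lines.append(f"Components: {src}")
        for label, family, xs in (
            ("MBD vs age [%]", self.mbd_family, ages),
            ("CBT vs age [mm]", self.cbt_family, ages),
            ("mAs vs CBT [mAs]", self.mas_family, (30, 55, 80)),
        ):
            lines.append("")
            lines.append(f"{label} percentile curves at x = {tuple(xs)}")
            for level in (5, 25, 50, 75, 95):
                vals = ", ".join(f"{eval_curve(family[level], x):8.2f}" for x in xs)
                lines.append(f"  p{level:<3d} {vals}")
        lines.append("")
        lines.append("kVp / target-filter selection (CBT bins):")
        for low, high, kvp, tf in self.kvp_tf_lookup.bins:
            lines.append(f"  {low:3d}-{high:3d} mm -> {kvp} kVp {tf}")
        return "\n".join(lines)

    def plot_family(self, quantity: Quantity | str, ax=None):
        """Plot a family's 20 percentile curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        quantity = Quantity(quantity)
        family = {
            Quantity.MBD_VS_AGE: self.mbd_family,
            Quantity.CBT_VS_AGE: self.cbt_family,
            Quantity.MAS_VS_CBT: self.mas_family,
        }[quantity]
        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(*family.domain, 200)
        for level in PERCENTILE_LEVELS:
            ax.plot(xs, np.polyval(family[level].coefficients, xs), lw=0.8)
        ax.set_xlabel("age [years]" if "age" in quantity.value else "CBT [mm]")
        ax.set_ylabel(quantity.value)
        return ax
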