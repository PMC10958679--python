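"""Packaged reference data: the published percentile-curve coefficients,
kVp/T-F lookup, per-category median doses and LAR cubics.

Coefficients are shipped at full printed precision so the published curves
are reproduced exactly.  All loaders return the package's domain objects
and cache on first use.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .curves import PercentileCurve, PercentileFamily, Quantity
from .exposure import KvpTfLookup
from .risk import CategoryMGDTable, LARModel


def _data_path(name: str):
    return resources.files("mammodose.data").joinpath(name)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path)


@lru_cache(maxsize=None)
def load_percentile_family(quantity: Quantity | str) -> PercentileFamily:
    """One of the three published percentile families."""
    quantity = Quantity(quantity)
    df = _read_csv("percentile_curves.csv")
    sub = df[df["quantity"] == quantity.value]
    curves = {}
    for _, row in sub.iterrows():
        coeffs = [row["a"], row["b"], row["c"]]
        if pd.notna(row["d"]):
            coeffs.append(row["d"])
        curves[int(row["percentile"])] = PercentileCurve(int(row["percentile"]), tuple(coeffs))
    return PercentileFamily(quantity=quantity, curves=curves)


def load_all_families() -> dict[Quantity, PercentileFamily]:
    return {q: load_percentile_family(q) for q in Quantity}


@lru_cache(maxsize=None)
def load_kvp_tf_lookup() -> KvpTfLookup:
    """The published Hologic Selenia Dimensions kVp/T-F selection table."""
    df = _read_csv("kvp_tf_lookup.csv")
    bins = tuple(
        (int(r.cbt_low_mm), int(r.cbt_high_mm), int(r.kvp), str(r.target_filter))
        for r in df.itertuples()
    )
    return KvpTfLookup(bins)


@lru_cache(maxsize=None)
def load_category_median_mgd() -> CategoryMGDTable:
    """Per-category median MGD at each screening age 40-75 (training cohort)."""
    df = _read_csv("category_median_mgd.csv").sort_values("age")
    return CategoryMGDTable(
        {cat: tuple(df[cat].astype(float)) for cat in ("low", "medium", "high")}
    )


@lru_cache(maxsize=None)
def load_lar_model() -> LARModel:
    """The LAR cubic coefficients and BEIR VII female-breast anchors."""
    coeffs = _read_csv("lar_coefficients.csv")
    mapping = {
        (str(r.endpoint), float(r.ddref)): (float(r.a), float(r.b), float(r.c), float(r.d))
        for r in coeffs.itertuples()
    }
    anchors_df = _read_csv("lar_anchors.csv")
    anchors = {
        "incidence": {
            int(r.age): float(r.incidence_per_100k_per_0p1Gy) for r in anchors_df.itertuples()
        },
        "mortality": {
            int(r.age): float(r.mortality_per_100k_per_0p1Gy) for r in anchors_df.itertuples()
        },
    }
    return LARModel(coefficients=mapping, anchors=anchors)
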