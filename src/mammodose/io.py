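"""File formats and the end-to-end pipeline.

CSV is the interchange format throughout (visit metadata emulates a
DICOM-header export); QA configuration is YAML or JSON with mandatory
distance units; dose profiles and risk reports are written as CSV plus a
schema-versioned JSON summary.  All logging goes to standard error and
never mixes with machine-readable output, and the pipeline is a pure
function of its input files.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .curves import PercentileCurve, PercentileFamily, Quantity
from .dosimetry import DoseProfile, FactorTables, QAParameters, predict_lifetime_doses
from .exposure import SCREENING_AGES, ExposurePlan, KvpTfLookup, build_exposure_plan
from .records import ImageRecord, VisitRecord, VisitSummary, summarise_visit
from .risk import (
    DEFAULT_BOUNDARIES,
    DoseCategoryBoundaries,
    LARModel,
    CategoryMGDTable,
    RiskReport,
    ScreeningRegimen,
    assign_category,
    build_regimen,
    build_risk_report,
)

__all__ = [
    "VISIT_COLUMNS",
    "RejectedRow",
    "SchemaError",
    "read_visits",
    "write_visits",
    "read_qa_config",
    "write_qa_config",
    "read_factor_tables",
    "write_factor_tables",
    "read_percentile_family",
    "write_percentile_family",
    "read_kvp_tf_lookup",
    "write_kvp_tf_lookup",
    "write_exposure_plan",
    "write_dose_profile",
    "risk_report_payload",
    "write_risk_report",
    "parse_regimen_spec",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

VISIT_COLUMNS = (
    "woman_id", "visit_id", "age_years", "laterality", "view", "mbd_pct",
    "cbt_mm", "kvp", "mas", "target_filter", "detector_id", "model_name",
)
OPTIONAL_VISIT_COLUMNS = ("hvl_mm_al",)


class SchemaError(ValueError):
    """An input file is missing mandatory structure (columns, header, rows)."""


@dataclass(frozen=True)
class RejectedRow:
    row_number: int
    reason: str


def _validate_image_row(row: dict) -> str | None:
    """Reason the row is invalid, or None if acceptable."""
    try:
        mbd = float(row["mbd_pct"])
        cbt = float(row["cbt_mm"])
        kvp = int(float(row["kvp"]))
        mas = float(row["mas"])
        age = int(float(row["age_years"]))
    except (TypeError, ValueError):
        return "non-numeric value in a numeric column"
    if not 0 <= mbd <= 100:
        return "mbd_pct out of range"
    if not 0 < cbt < 200:
        return "cbt_mm out of range"
    if not 20 <= kvp <= 49:
        return "kvp out of range"
    if mas <= 0:
        return "mas must be positive"
    if not 40 <= age <= 75:
        return "age_years outside the accepted screening range 40-75"
    if row["laterality"] not in ("L", "R"):
        return "laterality must be L or R"
    if row["view"] not in ("MLO", "CC"):
        return "view must be MLO or CC"
    return None


def read_visits(path: str | Path) -> tuple[list[VisitRecord], list[RejectedRow]]:
    """Parse a visit-metadata CSV into validated records plus a rejects list.

    Rows are grouped into visits by (woman_id, visit_id); malformed rows
    are collected with a reason rather than aborting the read.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file (no header row)")
        missing = [c for c in VISIT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns: {', '.join(missing)}")
        grouped: dict[tuple[str, str], list] = {}
        ages: dict[tuple[str, str], int] = {}
        rejects: list[RejectedRow] = []
        for i, row in enumerate(reader, start=2):  # data starts at line 2
            reason = _validate_image_row(row)
            if reason is not None:
                logger.warning("%s line %d rejected: %s", path, i, reason)
                rejects.append(RejectedRow(i, reason))
                continue
            key = (row["woman_id"], row["visit_id"])
            hvl = row.get("hvl_mm_al")
            grouped.setdefault(key, []).append(
                ImageRecord(
                    laterality=row["laterality"],
                    view=row["view"],
                    mbd_pct=float(row["mbd_pct"]),
                    cbt_mm=float(row["cbt_mm"]),
                    kvp=int(float(row["kvp"])),
                    mas=float(row["mas"]),
                    target_filter=row["target_filter"],
                    detector_id=row.get("detector_id", "") or "",
                    model_name=row.get("model_name", "") or "",
                    hvl_mm_al=float(hvl) if hvl not in (None, "") else None,
                )
            )
            ages[key] = int(float(row["age_years"]))
    records = [
        VisitRecord(woman_id=w, visit_id=v, age_years=ages[(w, v)], images=tuple(imgs))
        for (w, v), imgs in grouped.items()
    ]
    return records, rejects


def write_visits(records: Iterable[VisitRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(VISIT_COLUMNS + OPTIONAL_VISIT_COLUMNS)
        for rec in records:
            for img in rec.images:
                writer.writerow(
                    [
                        rec.woman_id, rec.visit_id, rec.age_years, img.laterality,
                        img.view, f"{img.mbd_pct:.4f}", f"{img.cbt_mm:.4f}", img.kvp,
                        f"{img.mas:.4f}", img.target_filter, img.detector_id,
                        img.model_name,
                        "" if img.hvl_mm_al is None else f"{img.hvl_mm_al:.4f}",
                    ]
                )


# ---------------------------------------------------------------------------
# QA configuration (YAML with JSON accepted)

def read_qa_config(path: str | Path, detector_id: str | None = None) -> QAParameters:
    """Read QA parameters from YAML/JSON; one block per detector ID.

    A flat single-unit file is also accepted.  ``distance_units: mm`` is
    mandatory; anything else is refused rather than converted.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: QA config must be a mapping")
    block = data
    if "tube_output_coeff" not in data:
        # keyed by detector ID
        if detector_id is not None:
            if detector_id not in data:
                raise SchemaError(f"{path}: no QA block for detector {detector_id!r}")
            block = data[detector_id]
        elif len(data) == 1:
            block = next(iter(data.values()))
        else:
            raise SchemaError(f"{path}: multiple detector blocks; pass detector_id")
    try:
        hvl_model = {
            tf: (float(v[0]), float(v[1])) for tf, v in block.get("hvl_model", {}).items()
        }
        return QAParameters(
            tube_output_coeff=float(block["tube_output_coeff"]),
            kvp_exponent=float(block["kvp_exponent"]),
            sid_mm=float(block["sid_mm"]),
            isd_mm=float(block["isd_mm"]),
            hvl_model=hvl_model,
            distance_units=str(block.get("distance_units", "")),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: QA config missing field {exc}") from None


def write_qa_config(qa: QAParameters, path: str | Path, detector_id: str = "default") -> None:
    payload = {
        detector_id: {
            "tube_output_coeff": qa.tube_output_coeff,
            "kvp_exponent": qa.kvp_exponent,
            "sid_mm": qa.sid_mm,
            "isd_mm": qa.isd_mm,
            "distance_units": qa.distance_units,
            "hvl_model": {tf: list(v) for tf, v in qa.hvl_model.items()},
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Factor tables: g.csv (hvl,cbt,value), c.csv (hvl,cbt,glandularity,value),
# s.csv (target_filter,value)

def read_factor_tables(g_path: str | Path, c_path: str | Path, s_path: str | Path) -> FactorTables:
    g = pd.read_csv(g_path)
    c = pd.read_csv(c_path)
    s = pd.read_csv(s_path)
    for df, cols, name in (
        (g, {"hvl", "cbt", "value"}, "g"),
        (c, {"hvl", "cbt", "glandularity", "value"}, "c"),
        (s, {"target_filter", "value"}, "s"),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise SchemaError(f"{name}-factor table missing columns {sorted(missing)}")

    g_hvl = np.sort(g["hvl"].unique())
    g_cbt = np.sort(g["cbt"].unique())
    g_grid = (
        g.set_index(["hvl", "cbt"])["value"].unstack().loc[g_hvl, g_cbt].to_numpy()
    )
    if np.isnan(g_grid).any():
        raise SchemaError("g-factor table is not a complete hvl x cbt grid")

    c_hvl = np.sort(c["hvl"].unique())
    c_cbt = np.sort(c["cbt"].unique())
    c_gland = np.sort(c["glandularity"].unique())
    pivot = c.set_index(["hvl", "cbt", "glandularity"])["value"]
    c_grid = np.full((len(c_hvl), len(c_cbt), len(c_gland)), np.nan)
    for (h, t, gl), v in pivot.items():
        c_grid[
            np.searchsorted(c_hvl, h), np.searchsorted(c_cbt, t), np.searchsorted(c_gland, gl)
        ] = v
    if np.isnan(c_grid).any():
        raise SchemaError("c-factor table is not a complete hvl x cbt x glandularity grid")

    return FactorTables(
        g_hvl=g_hvl, g_cbt=g_cbt, g_values=g_grid,
        c_hvl=c_hvl, c_cbt=c_cbt, c_gland=c_gland, c_values=c_grid,
        s_values=dict(zip(s["target_filter"], s["value"])),
    )


def write_factor_tables(
    tables: FactorTables, g_path: str | Path, c_path: str | Path, s_path: str | Path
) -> None:
    g_hvl, g_cbt = tables.g_axes
    rows = [
        {"hvl": h, "cbt": t, "value": tables.g_values[i, j]}
        for i, h in enumerate(g_hvl)
        for j, t in enumerate(g_cbt)
    ]
    pd.DataFrame(rows).to_csv(g_path, index=False)
    c_hvl, c_cbt, c_gland = tables.c_axes
    rows = [
        {"hvl": h, "cbt": t, "glandularity": gl, "value": tables.c_values[i, j, k]}
        for i, h in enumerate(c_hvl)
        for j, t in enumerate(c_cbt)
        for k, gl in enumerate(c_gland)
    ]
    pd.DataFrame(rows).to_csv(c_path, index=False)
    pd.DataFrame(
        [{"target_filter": tf, "value": v} for tf, v in tables.s_values.items()]
    ).to_csv(s_path, index=False)


# ---------------------------------------------------------------------------
# Percentile families and kVp/T-F lookup

def read_percentile_family(path: str | Path, quantity: Quantity | str) -> PercentileFamily:
    quantity = Quantity(quantity)
    df = pd.read_csv(path)
    sub = df[df["quantity"] == quantity.value] if "quantity" in df.columns else df
    curves = {}
    for _, row in sub.iterrows():
        coeffs = [row["a"], row["b"], row["c"]]
        if "d" in row and pd.notna(row["d"]):
            coeffs.append(row["d"])
        curves[int(row["percentile"])] = PercentileCurve(int(row["percentile"]), tuple(coeffs))
    return PercentileFamily(quantity=quantity, curves=curves)


def write_percentile_family(family: PercentileFamily, path: str | Path) -> None:
    rows = []
    for curve in family:
        coeffs = list(curve.coefficients) + [""] * (4 - len(curve.coefficients))
        rows.append(
            {"quantity": Quantity(family.quantity).value, "percentile": curve.percentile,
             "a": coeffs[0], "b": coeffs[1], "c": coeffs[2], "d": coeffs[3]}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_kvp_tf_lookup(path: str | Path) -> KvpTfLookup:
    df = pd.read_csv(path)
    cols = {"cbt_low_mm", "cbt_high_mm", "kvp", "target_filter"}
    alt = {"cbt_low", "cbt_high", "kvp", "target_filter"}
    if cols <= set(df.columns):
        lo_col, hi_col = "cbt_low_mm", "cbt_high_mm"
    elif alt <= set(df.columns):
        lo_col, hi_col = "cbt_low", "cbt_high"
    else:
        raise SchemaError(f"{path}: lookup needs columns {sorted(cols)}")
    return KvpTfLookup(
        tuple(
            (int(r[lo_col]), int(r[hi_col]), int(r["kvp"]), str(r["target_filter"]))
            for _, r in df.iterrows()
        )
    )


def write_kvp_tf_lookup(lookup: KvpTfLookup, path: str | Path) -> None:
    pd.DataFrame(
        lookup.bins, columns=["cbt_low_mm", "cbt_high_mm", "kvp", "target_filter"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Output artifacts

def write_exposure_plan(plan: ExposurePlan, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"age": e.age, "mbd_pct": e.mbd_pct, "cbt_mm": e.cbt_mm, "kvp": e.kvp,
             "mas": e.mas, "target_filter": e.target_filter}
            for e in plan.entries
        ]
    ).to_csv(path, index=False)


def write_dose_profile(
    profile: DoseProfile, csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    pd.DataFrame({"age": SCREENING_AGES, "mgd_mGy": profile.per_age_mgd}).to_csv(
        csv_path, index=False
    )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                {"schema_version": REPORT_SCHEMA_VERSION,
                 "mgd_msr_mGy": profile.mgd_msr, "category": profile.category},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def risk_report_payload(report: RiskReport) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "category": report.category,
        "regimen": {"name": report.regimen.name, "visit_ages": list(report.regimen.visit_ages)},
        "ddref": report.ddref,
        "individual_exploratory": report.individual,
        "per_visit": [
            {"age": v.age, "mgd_mGy": v.mgd_mGy,
             "lar_incidence_per_100k_per_mGy": v.lar_incidence,
             "lar_mortality_per_100k_per_mGy": v.lar_mortality,
             "risk_incidence_per_100k": v.risk_incidence,
             "risk_mortality_per_100k": v.risk_mortality}
            for v in report.per_visit
        ],
        "ler_incidence_per_100k": report.ler_incidence,
        "ler_mortality_per_100k": report.ler_mortality,
        "percent_incidence": round(report.percent_incidence, 3),
        "percent_mortality": round(report.percent_mortality, 3),
    }


def write_risk_report(
    report: RiskReport, json_path: str | Path, csv_path: str | Path | None = None
) -> None:
    with open(json_path, "w") as fh:
        json.dump(risk_report_payload(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if csv_path is not None:
        pd.DataFrame(
            [
                {"age": v.age, "mgd_mGy": v.mgd_mGy, "lar_incidence": v.lar_incidence,
                 "lar_mortality": v.lar_mortality, "risk_incidence": v.risk_incidence,
                 "risk_mortality": v.risk_mortality}
                for v in report.per_visit
            ]
        ).to_csv(csv_path, index=False)


def parse_regimen_spec(spec: str) -> ScreeningRegimen:
    """Parse a CLI regimen spec: preset name, 'start:end:interval', or a
    comma-separated age list."""
    if ":" in spec:
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError("interval regimen spec must be start:end:interval")
        return build_regimen(
            start_age=int(parts[0]), end_age=int(parts[1]), interval_years=int(parts[2])
        )
    if "," in spec:
        return build_regimen([int(a) for a in spec.split(",")])
    return build_regimen(spec)


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass(frozen=True)
class PipelineResult:
    summary: VisitSummary
    plan: ExposurePlan
    profile: DoseProfile
    report: RiskReport


def run_pipeline(
    visits_path: str | Path,
    qa: QAParameters,
    tables: FactorTables,
    regimen: ScreeningRegimen,
    ddref: float,
    *,
    mbd_family: PercentileFamily | None = None,
    cbt_family: PercentileFamily | None = None,
    mas_family: PercentileFamily | None = None,
    lookup: KvpTfLookup | None = None,
    category_table: CategoryMGDTable | None = None,
    lar_model: LARModel | None = None,
    boundaries: DoseCategoryBoundaries = DEFAULT_BOUNDARIES,
    out_dir: str | Path | None = None,
) -> dict[str, PipelineResult]:
    """Summarise, forecast, dose and risk-score every woman in a visit file.

    Component models default to the packaged published ones.  Per-woman
    failures are logged and skipped; if every woman fails, a ``SchemaError``
    is raised.  With ``out_dir`` set, per-woman dose profiles and risk
    reports plus a rejects CSV are written there; outputs are sorted by
    woman ID and carry no timestamps, so repeated runs are identical.
    """
    from . import datasets  # deferred: packaged defaults only when needed

    mbd_family = mbd_family or datasets.load_percentile_family(Quantity.MBD_VS_AGE)
    cbt_family = cbt_family or datasets.load_percentile_family(Quantity.CBT_VS_AGE)
    mas_family = mas_family or datasets.load_percentile_family(Quantity.MAS_VS_CBT)
    lookup = lookup or datasets.load_kvp_tf_lookup()
    category_table = category_table or datasets.load_category_median_mgd()
    lar_model = lar_model or datasets.load_lar_model()

    records, rejects = read_visits(visits_path)
    if not records:
        raise SchemaError(f"{visits_path}: no valid visit rows")

    # first visit per woman = lowest age, then visit_id for determinism
    first_visits: dict[str, VisitRecord] = {}
    for rec in sorted(records, key=lambda r: (r.woman_id, r.age_years, r.visit_id)):
        first_visits.setdefault(rec.woman_id, rec)

    results: dict[str, PipelineResult] = {}
    for woman_id in sorted(first_visits):
        rec = first_visits[woman_id]
        try:
            summary = summarise_visit(rec)
            plan = build_exposure_plan(
                age=summary.age_years, mbd_pct=summary.mbd_pct, cbt_mm=summary.cbt_mm,
                mas=summary.mas, mbd_family=mbd_family, cbt_family=cbt_family,
                mas_family=mas_family, lookup=lookup,
                observed_kvp=summary.kvp, observed_tf=summary.target_filter,
            )
            profile = predict_lifetime_doses(plan, qa, tables)
            category = assign_category(profile.mgd_msr, boundaries)
            profile = profile.with_category(category)
            report = build_risk_report(category, regimen, ddref, category_table, lar_model)
        except (ValueError, KeyError) as exc:
            logger.warning("woman %s failed and was skipped: %s", woman_id, exc)
            continue
        results[woman_id] = PipelineResult(summary, plan, profile, report)

    if not results:
        raise SchemaError("every woman in the input failed processing")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "rejects.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row_number", "reason"])
            for rej in rejects:
                writer.writerow([rej.row_number, rej.reason])
        for woman_id, res in results.items():
            write_dose_profile(
                res.profile,
                out_dir / f"{woman_id}_dose_profile.csv",
                out_dir / f"{woman_id}_dose_summary.json",
            )
            write_risk_report(res.report, out_dir / f"{woman_id}_risk.json")
    return results
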