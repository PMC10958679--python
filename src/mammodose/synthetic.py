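"""Seeded synthetic cohorts and fixture conversion-factor tables.

The generator produces screening-visit records with the statistical
structure the prediction model assumes: each woman occupies one percentile
level of the MBD/CBT growth-curve families, her acquisition follows the
kVp/T-F selection rule and the mAs percentile curves, and measurement
noise is additive Gaussian on MBD/CBT (truncated to physical bounds) and
multiplicative log-normal on mAs.  That makes every downstream stage —
family fitting, lookup derivation, dosimetry, categorisation — testable by
round trip against known ground truth without any external data.

The fixture factor tables are smooth, positive and physically shaped
(g decreasing with thickness, c equal to 1 at 50% glandularity and
decreasing above it, s near 1) but deliberately synthetic: they stand in
for the published dosimetric factor grids, which users supply in the same
CSV format for real work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import PERCENTILE_LEVELS, PercentileFamily, Quantity, eval_curve
from .dosimetry import FactorTables, QAParameters
from .exposure import KvpTfLookup, lookup_kvp_tf
from .records import ImageRecord, VisitRecord

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "simulate_exposures_from_lookup",
    "generate_factor_tables",
    "default_qa_parameters",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for a synthetic screening cohort.

    Defaults emulate a first-visit screening population: ages uniform over
    40-75, women spread uniformly over the 20 percentile levels, modest
    measurement noise, and four images (2 MLO + 2 CC) per visit.
    """

    n_women: int = 1000
    seed: int = 0
    age_low: int = 40
    age_high: int = 75
    mbd_noise_sd: float = 1.0  # percentage points
    cbt_noise_sd: float = 2.0  # mm
    mas_noise_sd: float = 0.05  # log-normal sigma (relative)
    kvp_noise_rate: float = 0.0  # fraction of images with a perturbed kVp
    images_per_visit: int = 4
    percentile_weights: tuple[float, ...] | None = None  # over the 20 levels

    def __post_init__(self) -> None:
        if self.n_women <= 0:
            raise ValueError("n_women must be > 0")
        if min(self.mbd_noise_sd, self.cbt_noise_sd, self.mas_noise_sd) < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 <= self.kvp_noise_rate <= 1:
            raise ValueError("kvp_noise_rate must be in [0, 1]")
        if self.percentile_weights is not None and len(self.percentile_weights) != len(
            PERCENTILE_LEVELS
        ):
            raise ValueError("percentile_weights must have 20 entries")


def generate_cohort(
    spec: CohortSpec,
    mbd_family: PercentileFamily,
    cbt_family: PercentileFamily,
    mas_family: PercentileFamily,
    lookup: KvpTfLookup,
) -> list[VisitRecord]:
    """One first-visit record per woman, deterministic given ``spec.seed``."""
    if Quantity(mbd_family.quantity) is not Quantity.MBD_VS_AGE:
        raise ValueError("mbd_family must be the MBD-vs-age family")
    rng = np.random.default_rng(spec.seed)
    weights = None
    if spec.percentile_weights is not None:
        w = np.asarray(spec.percentile_weights, dtype=float)
        weights = w / w.sum()

    records: list[VisitRecord] = []
    for i in range(spec.n_women):
        age = int(rng.integers(spec.age_low, spec.age_high + 1))
        level = int(rng.choice(PERCENTILE_LEVELS, p=weights))
        mbd_true = eval_curve(mbd_family[level], age)
        cbt_true = eval_curve(cbt_family[level], age)
        images = []
        for j in range(spec.images_per_visit):
            mbd = float(np.clip(mbd_true + rng.normal(0, spec.mbd_noise_sd), 0.0, 100.0))
            cbt = float(np.clip(cbt_true + rng.normal(0, spec.cbt_noise_sd), 20.0, 110.0))
            kvp, tf = lookup_kvp_tf(lookup, cbt)
            if spec.kvp_noise_rate and rng.random() < spec.kvp_noise_rate:
                kvp = int(np.clip(kvp + rng.choice([-2, -1, 1, 2]), 20, 49))
            mas_true = max(eval_curve(mas_family[level], cbt), 1.0)
            mas = float(mas_true * np.exp(rng.normal(0, spec.mas_noise_sd)))
            images.append(
                ImageRecord(
                    laterality="L" if j % 2 == 0 else "R",
                    view="MLO" if j < 2 else "CC",
                    mbd_pct=mbd,
                    cbt_mm=cbt,
                    kvp=kvp,
                    mas=mas,
                    target_filter=tf,
                    detector_id="SYN01",
                    model_name="synthetic",
                )
            )
        records.append(
            VisitRecord(
                woman_id=f"W{i:06d}", visit_id=f"W{i:06d}-V1", age_years=age,
                images=tuple(images),
            )
        )
    return records


def simulate_exposures_from_lookup(
    lookup: KvpTfLookup,
    n: int,
    seed: int = 0,
    *,
    kvp_noise_rate: float = 0.0,
) -> list[tuple[float, int, str]]:
    """(CBT, kVp, T/F) triples drawn from the selection rule itself.

    CBT is uniform over the full 20-110 mm table range, so every bin is
    exercised — the round-trip oracle for lookup derivation.  With
    ``kvp_noise_rate`` a fraction of records carries a perturbed kVp,
    testing the mode's robustness to contamination.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 20.0, 110.0
    triples: list[tuple[float, int, str]] = []
    for _ in range(n):
        cbt = float(rng.uniform(lo, hi))
        kvp, tf = lookup_kvp_tf(lookup, cbt)
        if kvp_noise_rate and rng.random() < kvp_noise_rate:
            kvp = int(rng.integers(24, 40))
        triples.append((cbt, kvp, tf))
    return triples


def generate_factor_tables(
    seed: int = 0,
    *,
    hvl_nodes: tuple[float, ...] = (0.30, 0.40, 0.50, 0.60, 0.70),
    cbt_nodes: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 110.0),
    gland_nodes: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0),
) -> FactorTables:
    """Smooth synthetic g/c/s fixture grids, deterministic given ``seed``.

    g lies in (0, 1], decreases with CBT and increases with HVL; c equals
    1 exactly at 50% glandularity and decreases above it; s is near 1 per
    target/filter.  Shapes mimic the published factor tables; values do
    not reproduce them.
    """
    rng = np.random.default_rng(seed)
    hvl = np.asarray(hvl_nodes)
    cbt = np.asarray(cbt_nodes)
    gland = np.asarray(gland_nodes)

    # g: kerma-to-dose efficiency falls roughly exponentially with thickness
    # and rises with beam hardness.
    H, C = np.meshgrid(hvl, cbt, indexing="ij")
    g_values = (0.35 + 0.5 * (H - hvl.min())) * np.exp(-C / 80.0)
    g_values *= 1.0 + rng.uniform(-0.02, 0.02, size=g_values.shape)
    g_values = np.clip(g_values, 1e-3, 1.0)

    # c: unity at the 50% reference glandularity, decreasing with
    # glandularity above it (denser breasts absorb less per gland gram).
    H3, C3, G3 = np.meshgrid(hvl, cbt, gland, indexing="ij")
    c_values = 1.0 - 0.004 * (G3 - 50.0) * (1.0 + 0.2 * (C3 - cbt.min()) / np.ptp(cbt))
    c_values = np.clip(c_values, 0.5, 1.6)

    s_values = {
        "W/Rh": float(1.0 + rng.uniform(-0.05, 0.05)),
        "W/Ag": float(1.0 + rng.uniform(-0.05, 0.05)),
    }
    return FactorTables(
        g_hvl=hvl, g_cbt=cbt, g_values=g_values,
        c_hvl=hvl, c_cbt=cbt, c_gland=gland, c_values=c_values,
        s_values=s_values,
    )


def default_qa_parameters() -> QAParameters:
    """Plausible Hologic-like QA constants for tests and examples.

    Geometry is a 700 mm SID with a 25 mm receptor-to-support gap and HVL
    linear in kVp per target/filter.  The output coefficient is calibrated
    (jointly with the fixture factor tables) so that a median woman's
    predicted visit doses land in the low-mGy range observed in screening
    dose audits; it is a fixture constant, not a published survey value.
    """
    return QAParameters(
        tube_output_coeff=0.85,
        kvp_exponent=3.0,
        sid_mm=700.0,
        isd_mm=25.0,
        hvl_model={"W/Rh": (0.08, 0.0145), "W/Ag": (0.10, 0.0150)},
    )
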