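"""Visit and image records: the per-image screening-visit metadata the
pipeline consumes (an extract of the acquisition DICOM headers plus an
area-density estimate), and their per-visit summary."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import fmean

__all__ = ["ImageRecord", "VisitRecord", "VisitSummary", "summarise_visit"]

VIEWS = ("MLO", "CC")
LATERALITIES = ("L", "R")


@dataclass(frozen=True)
class ImageRecord:
    """One mammographic exposure within a visit."""

    laterality: str
    view: str
    mbd_pct: float
    cbt_mm: float
    kvp: int
    mas: float
    target_filter: str
    detector_id: str = ""
    model_name: str = ""
    hvl_mm_al: float | None = None


@dataclass(frozen=True)
class VisitRecord:
    """One screening visit: 1-4+ images for one woman at one age."""

    woman_id: str
    visit_id: str
    age_years: int
    images: tuple[ImageRecord, ...]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("a visit must contain at least one image")


@dataclass(frozen=True)
class VisitSummary:
    """First-visit inputs to the prediction pipeline, averaged over images."""

    woman_id: str
    visit_id: str
    age_years: int
    mbd_pct: float
    cbt_mm: float
    mas: float
    kvp: int
    target_filter: str
    n_images: int


def summarise_visit(record: VisitRecord) -> VisitSummary:
    """Per-visit summary: arithmetic means of MBD/CBT/mAs across images,
    modal kVp and target/filter (ties toward the lower kVp)."""
    imgs = record.images
    kvp_counts = Counter(i.kvp for i in imgs)
    top = max(kvp_counts.values())
    kvp = min(k for k, n in kvp_counts.items() if n == top)
    tf_counts = Counter(i.target_filter for i in imgs)
    tf_top = max(tf_counts.values())
    tf_order = {"W/Rh": 0, "W/Ag": 1}  # ties favour the softer spectrum
    tf = min((t for t, n in tf_counts.items() if n == tf_top), key=lambda t: tf_order.get(t, 9))
    if len(tf_counts) > 1:
        import logging

        logging.getLogger(__name__).warning(
            "visit %s mixes target/filter values %s; using modal %s",
            record.visit_id, dict(tf_counts), tf,
        )
    return VisitSummary(
        woman_id=record.woman_id,
        visit_id=record.visit_id,
        age_years=record.age_years,
        mbd_pct=fmean(i.mbd_pct for i in imgs),
        cbt_mm=fmean(i.cbt_mm for i in imgs),
        mas=fmean(i.mas for i in imgs),
        kvp=kvp,
        target_filter=tf,
        n_images=len(imgs),
    )
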