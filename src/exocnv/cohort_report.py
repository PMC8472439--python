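"""Cohort-level diagnostic-yield, size-class and concordance summaries.

Patients can have several disease categories analysed at once; per-category
yields therefore use category patient counts as denominators, and a
multi-category patient contributes to each of their categories.  All
percentages are computed from the stored integer counts and rounded to one
decimal only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import ValidationError

#: Disease-category vocabulary used in cohort records.
CATEGORIES = (
    "NDD", "neurodegeneration", "renal", "heart", "connective", "vision",
    "hearing_loss", "metabolic", "neuromuscular", "blood_immune",
    "mitochondrial", "pulmonary_fibrosis", "diverse",
)

OUTCOMES = (
    "positive_snv", "positive_cnv", "positive_both", "vus_snv", "vus_cnv",
    "negative",
)
POSITIVE_OUTCOMES = {"positive_snv", "positive_cnv", "positive_both"}
CNV_DIAGNOSED = {"positive_cnv", "positive_both"}

ACGH_STATUSES = ("before_ngs", "validation", "after_ngs", "none")


@dataclass
class CohortRecord:
    patient_id: str
    categories: tuple[str, ...]
    outcome: str
    acgh_status: str = "none"

    def __post_init__(self):
        if not self.categories:
            raise ValidationError(f"{self.patient_id}: at least one category required")
        for c in self.categories:
            if c not in CATEGORIES:
                raise ValidationError(f"{self.patient_id}: unknown category {c!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"{self.patient_id}: unknown outcome {self.outcome!r}")
        if self.acgh_status not in ACGH_STATUSES:
            raise ValidationError(f"{self.patient_id}: unknown acgh_status")


def records_from_frame(df: pd.DataFrame) -> list[CohortRecord]:
    """Build records from a cohort table (categories ';'-joined)."""
    return [
        CohortRecord(
            patient_id=str(r["patient_id"]),
            categories=tuple(str(r["categories"]).split(";")),
            outcome=str(r["outcome"]),
            acgh_status=str(r.get("acgh_status", "none")),
        )
        for _, r in df.iterrows()
    ]


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "categories": [";".join(r.categories) for r in records],
        "outcome": [r.outcome for r in records],
        "acgh_status": [r.acgh_status for r in records],
    })


# ---------------------------------------------------------------------------
# Yield
# ---------------------------------------------------------------------------

@dataclass
class YieldReport:
    n_patients: int
    n_positive: int
    n_vus: int
    n_negative: int
    per_category: pd.DataFrame  # category, n, positive, rate_pct, vus, negative

    @property
    def overall_rate_pct(self) -> float:
        return round(100.0 * self.n_positive / self.n_patients, 1)


def yield_report(records: list[CohortRecord]) -> YieldReport:
    """Overall and per-category diagnostic yield."""
    if not records:
        raise ValidationError("empty cohort")
    n = len(records)
    n_pos = sum(r.outcome in POSITIVE_OUTCOMES for r in records)
    n_vus = sum(r.outcome in ("vus_snv", "vus_cnv") for r in records)
    n_neg = sum(r.outcome == "negative" for r in records)
    rows = []
    for cat in CATEGORIES:
        members = [r for r in records if cat in r.categories]
        if not members:
            continue
        pos = sum(r.outcome in POSITIVE_OUTCOMES for r in members)
        rows.append({
            "category": cat,
            "n": len(members),
            "positive": pos,
            "rate_pct": round(100.0 * pos / len(members), 1),
            "vus": sum(r.outcome in ("vus_snv", "vus_cnv") for r in members),
            "negative": sum(r.outcome == "negative" for r in members),
        })
    per_cat = pd.DataFrame(rows).sort_values("rate_pct", ascending=False).reset_index(drop=True)
    return YieldReport(n, n_pos, n_vus, n_neg, per_cat)


def cnv_yield_delta(records: list[CohortRecord]) -> tuple[int, float]:
    """Patients whose diagnosis required the CNV pipeline: count and fraction."""
    n = len(records)
    count = sum(r.outcome in CNV_DIAGNOSED for r in records)
    return count, (100.0 * count / n if n else 0.0)


# ---------------------------------------------------------------------------
# Size classes
# ---------------------------------------------------------------------------

def size_class_summary(cnvs: pd.DataFrame) -> pd.DataFrame:
    """Per-patient size-class partition of diagnostic CNVs.

    ``cnvs`` needs columns ``patient_id`` and ``size_class`` (a patient with
    several CNVs is classed by their largest event, i.e. the maximal class
    in the order exon_level < gene_size < large).  Returns counts and
    one-decimal percentages per class.
    """
    order = ["exon_level", "gene_size", "large"]
    if cnvs.empty:
        return pd.DataFrame({"size_class": order, "count": 0, "pct": 0.0})
    rank = {c: i for i, c in enumerate(order)}
    per_patient = (
        cnvs.assign(_rank=cnvs["size_class"].map(rank))
        .groupby("patient_id")["_rank"].max()
    )
    n = len(per_patient)
    rows = []
    for cls in order:
        count = int((per_patient == rank[cls]).sum())
        rows.append({"size_class": cls, "count": count,
                     "pct": round(100.0 * count / n, 1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orthogonal-assay concordance
# ---------------------------------------------------------------------------

def acgh_concordance(records: pd.DataFrame) -> dict:
    """Detected/undetected breakdown for microarray VUS CNVs re-examined in
    the sequencing data.

    ``records`` needs boolean columns ``has_ngs_targets`` and
    ``polymorphic_in_batch``: a CNV is recoverable from sequencing only when
    capture targets exist in the region and it is not a batch/population
    polymorphism suppressed by frequency filtering.
    """
    has = records["has_ngs_targets"].astype(bool)
    poly = records["polymorphic_in_batch"].astype(bool)
    detected = int((has & ~poly).sum())
    return {
        "n": int(len(records)),
        "detected": detected,
        "undetected": {
            "no_ngs_targets": int((~has).sum()),
            "polymorphic": int((has & poly).sum()),
        },
    }


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_report(records: list[CohortRecord],
                  size_classes: pd.DataFrame | None = None) -> str:
    rep = yield_report(records)
    cnv_count, cnv_pct = cnv_yield_delta(records)
    lines = [
        f"Cohort: {rep.n_patients} patients",
        f"Positive (SNV and/or CNV): {rep.n_positive} ({rep.overall_rate_pct}%)",
        f"CNV-diagnosed: {cnv_count} ({round(cnv_pct, 1)}%)",
        f"VUS: {rep.n_vus}   Negative: {rep.n_negative}",
        "",
        "Per-category yield:",
    ]
    for _, r in rep.per_category.iterrows():
        lines.append(
            f"  {r['category']:<20} {r['positive']:>3}/{r['n']:<3} ({r['rate_pct']}%)"
        )
    if size_classes is not None and not size_classes.empty:
        lines += ["", "Diagnostic CNV size classes:"]
        for _, r in size_classes.iterrows():
            lines.append(f"  {r['size_class']:<12} {r['count']:>3} ({r['pct']}%)")
    return "\n".join(lines)
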