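"""Panel filtering and pathogenicity classification of annotated CNVs.

Classification follows a transparent five-rule cascade built from the three
evidence classes used in diagnostic CNV review — rarity, phenotype-matching
disease genes, and recurrent pathogenic regions — plus gene dosage maps
(ClinGen haploinsufficiency / triplosensitivity):

R0  common in the batch or a CNV database        -> benign
R1  matches a known recurrent pathogenic region  -> pathogenic
R2  loss over an HI-3 gene / gain over a TS-3 gene
    that matches the phenotype                   -> pathogenic
R3  hits a disease gene matching the phenotype
    without dosage-3 support                     -> likely_pathogenic
R4  rare and gene-impacting, no phenotype match  -> VUS
    otherwise                                    -> likely_benign

The engine is table-driven: known regions and dosage scores are plain
tables, so a point-based scheme can be swapped in without touching callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotate import AnnotatedCnv, reciprocal_overlap
from .io_formats import ValidationError, _norm_chrom

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic")

#: Conventional CNV rarity bound: population/batch frequency above this is
#: treated as polymorphic.
DEFAULT_RARITY_MAX = 0.01


@dataclass
class ClassifiedCnv:
    annotated: AnnotatedCnv
    in_panel: bool
    classification: str
    evidence: list[tuple[str, str]] = field(default_factory=list)

    @property
    def call(self):
        return self.annotated.call


def panel_filter(
    cnvs: list[AnnotatedCnv] | list[ClassifiedCnv],
    panel: set[str],
    mode: str = "panel",
) -> list:
    """Set ``in_panel`` and, in panel mode, drop out-of-panel CNVs.

    A CNV is in-panel when at least one overlapped gene with coding overlap
    (>=1 affected exon) belongs to the panel.  Genome-wide mode keeps every
    CNV — the recommended practice for patients unsolved by panel analysis.
    """
    if mode not in ("panel", "genome_wide"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "panel" and not panel:
        raise ValidationError("panel mode requires a non-empty gene panel")

    def _in_panel(ann: AnnotatedCnv) -> bool:
        return any(g.gene in panel and g.n_exons >= 1 for g in ann.genes)

    out = []
    for c in cnvs:
        ann = c.annotated if isinstance(c, ClassifiedCnv) else c
        flag = _in_panel(ann)
        if isinstance(c, ClassifiedCnv):
            c.in_panel = flag
        if mode == "panel" and not flag:
            continue
        out.append(c)
    return out


def classify(
    cnv: AnnotatedCnv,
    rarity_max: float = DEFAULT_RARITY_MAX,
    phenotype_genes: set[str] | None = None,
    known_regions: pd.DataFrame | None = None,
    dosage_available: bool = True,
    ro_threshold: float = 0.5,
) -> ClassifiedCnv:
    """Run the rule cascade on one annotated CNV.

    ``known_regions`` rows need columns chrom, start, end, type (gain/loss);
    ``phenotype_genes`` is the union of genes in the requested panels.  The
    evidence list records every rule that fired, so the classification is
    reproducible from the evidence alone.
    """
    phenotype_genes = phenotype_genes or set()
    call = cnv.call
    evidence: list[tuple[str, str]] = []

    # R0 — frequency: polymorphic changes seen in controls or batch-mates.
    freq = max(cnv.batch_freq, cnv.db_freq)
    if freq > rarity_max:
        evidence.append(("R0", f"frequency {freq:.3f} > {rarity_max}: polymorphic"))
        return ClassifiedCnv(cnv, in_panel=False, classification="benign",
                             evidence=evidence)
    evidence.append(("R0", f"rare (max frequency {freq:.4f} <= {rarity_max})"))

    # R1 — known recurrent pathogenic region of matching direction.
    if known_regions is not None and not known_regions.empty:
        sub = known_regions[
            known_regions["chrom"].map(_norm_chrom) == _norm_chrom(call.chrom)
        ]
        for _, rec in sub.iterrows():
            if rec["type"] != call.type:
                continue
            if reciprocal_overlap(call.start, call.end, int(rec["start"]),
                                  int(rec["end"])) >= ro_threshold:
                name = rec.get("name", f"{rec['chrom']}:{rec['start']}-{rec['end']}")
                evidence.append(("R1", f"matches known pathogenic region {name}"))
                return ClassifiedCnv(cnv, in_panel=False,
                                     classification="pathogenic", evidence=evidence)

    coding_hits = [g for g in cnv.genes if g.n_exons >= 1]
    pheno_hits = [g for g in coding_hits if g.gene in phenotype_genes]

    # R2 — dosage-sensitive phenotype gene (HI 3 for losses, TS 3 for gains).
    if dosage_available:
        for g in pheno_hits:
            if not g.dosage:
                continue
            score = g.dosage.get("hi_score" if call.type == "loss" else "ts_score")
            if score == 3:
                kind = "haploinsufficient" if call.type == "loss" else "triplosensitive"
                evidence.append(("R2", f"{g.gene} is {kind} (score 3) and phenotype-matched"))
                return ClassifiedCnv(cnv, in_panel=True,
                                     classification="pathogenic", evidence=evidence)
    else:
        logger.warning("dosage table missing: dosage rules R2/R3 skipped")

    # R3 — disease gene matching the phenotype, without dosage-3 support.
    if dosage_available:
        for g in pheno_hits:
            if g.dosage and g.dosage.get("disease_flag"):
                evidence.append(("R3", f"{g.gene} is a phenotype-matched disease gene"))
                return ClassifiedCnv(cnv, in_panel=True,
                                     classification="likely_pathogenic",
                                     evidence=evidence)

    # R4 — rare, gene-impacting, but unconnected to the phenotype.
    if coding_hits:
        evidence.append(("R4", "rare gene-impacting CNV without phenotype match"))
        return ClassifiedCnv(cnv, in_panel=bool(pheno_hits),
                             classification="VUS", evidence=evidence)

    evidence.append(("R5", "no coding impact"))
    return ClassifiedCnv(cnv, in_panel=False, classification="likely_benign",
                         evidence=evidence)
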