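"""Post-calling annotation: merging, cytobands, genes, probes, frequencies.

Fragmented calls are merged when separated by fewer than 3 capture targets
with the same direction and ploidy, to undo splits caused by locally poor
coverage.  Each call is then decorated with its cytogenetic band span, the
genes and exon counts it hits, how many microarray (aCGH) and MLPA probes
fall inside it — and hence whether the orthogonal assays could confirm it
(>=3 consecutive aCGH probes, >=2 MLPA probes) — its distance in capture
targets from the chromosome termini, and its frequency in the batch and in
CNV databases (matched at >=50% reciprocal overlap by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .depth_model import CnvCall
from .io_formats import AnnotationTables, TargetGrid, ValidationError, _norm_chrom

#: Orthogonal-assay confirmation rules: minimum deviated probes.
MIN_ACGH_PROBES = 3
MIN_MLPA_PROBES = 2

#: Size-class boundaries (bp): single/few-exon events vs whole-gene events
#: vs events above the prenatal microarray reporting cut-off.
EXON_LEVEL_MAX = 5_000
LARGE_MIN = 400_000

#: A call within this many capture targets of a chromosome end is flagged
#: terminal (possible larger rearrangement).
TERMINAL_TARGETS = 10


@dataclass
class GeneHit:
    gene: str
    n_exons: int
    whole_gene: bool
    intronic_only: bool = False
    dosage: dict | None = None
    pseudogene_flag: bool = False


@dataclass
class AnnotatedCnv:
    """A CNV call plus everything the diagnostic review consults."""

    call: CnvCall
    cytoband: str = ""
    genes: list[GeneHit] = field(default_factory=list)
    probe_counts: dict[str, int] = field(default_factory=dict)
    detectable: dict[str, bool] = field(default_factory=dict)
    pter_targets: int = 0
    qter_targets: int = 0
    terminal: bool = False
    batch_freq: float = 0.0
    db_freq: float = 0.0
    size_class: str = ""


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _gap_targets(a: CnvCall, b: CnvCall) -> int:
    """Number of capture targets strictly between two calls on one chromosome."""
    first, second = (a, b) if a.first_target <= b.first_target else (b, a)
    return second.first_target - first.last_target - 1


def merge_calls(calls: list[CnvCall], grid: TargetGrid,
                max_gap: int = 3) -> list[CnvCall]:
    """Merge same-type, same-ploidy calls separated by fewer than 3 targets.

    Applied to fixpoint; idempotent and independent of input order.  Merged
    quality is the max of the parts, mean_ratio the target-count-weighted
    mean.  Overlapping calls of different ploidy indicate an upstream bug.
    """
    out = sorted(calls, key=lambda c: (c.chrom, c.first_target, c.last_target))
    for a, b in zip(out, out[1:]):
        if a.chrom == b.chrom and _gap_targets(a, b) < 0 and a.copy_number != b.copy_number:
            raise ValidationError(
                f"overlapping calls of different ploidy at {a.chrom}:{a.start}-{a.end}"
            )
    changed = True
    while changed:
        changed = False
        merged: list[CnvCall] = []
        for c in out:
            prev = merged[-1] if merged else None
            if (
                prev is not None
                and prev.chrom == c.chrom
                and prev.copy_number == c.copy_number
                and _gap_targets(prev, c) < max_gap
            ):
                w1, w2 = prev.n_targets, c.n_targets
                last = max(prev.last_target, c.last_target)
                combined = replace(
                    prev,
                    first_target=min(prev.first_target, c.first_target),
                    last_target=last,
                    start=min(prev.start, c.start),
                    end=max(prev.end, c.end),
                    n_targets=w1 + w2,
                    mean_ratio=(prev.mean_ratio * w1 + c.mean_ratio * w2) / (w1 + w2),
                    quality=max(prev.quality, c.quality),
                )
                merged[-1] = combined
                changed = True
            else:
                merged.append(c)
        out = merged
    return out


# ---------------------------------------------------------------------------
# Individual annotations
# ---------------------------------------------------------------------------

def cytoband_span(cnv: CnvCall, cytobands: pd.DataFrame) -> str:
    """ISCN-like band span, e.g. ``22q13.31q13.33`` or ``3p13``."""
    chrom = _norm_chrom(cnv.chrom)
    sub = cytobands[cytobands["chrom"].map(_norm_chrom) == chrom]
    hits = sub[(sub["start"] < cnv.end) & (sub["end"] > cnv.start)]
    if hits.empty:
        raise ValidationError(
            f"CNV {cnv.chrom}:{cnv.start}-{cnv.end} outside cytoband coverage"
        )
    hits = hits.sort_values("start")
    first, last = hits.iloc[0]["band"], hits.iloc[-1]["band"]
    return chrom + first + (last if last != first else "")


def gene_overlap(cnv: CnvCall, tables: AnnotationTables) -> list[GeneHit]:
    """Genes hit by the CNV with affected-exon counts and dosage annotations."""
    hits: list[GeneHit] = []
    for gm in tables.genes_on(cnv.chrom):
        if gm.tx_end <= cnv.start or gm.tx_start >= cnv.end:
            continue
        n_exons = sum(1 for s, e in gm.exons if s < cnv.end and e > cnv.start)
        dosage = tables.dosage_for(gm.gene)
        hits.append(GeneHit(
            gene=gm.gene,
            n_exons=n_exons,
            whole_gene=n_exons == len(gm.exons) and n_exons > 0,
            intronic_only=n_exons == 0,
            dosage=dosage,
            pseudogene_flag=bool(dosage and dosage.get("pseudogene_flag")),
        ))
    hits.sort(key=lambda h: h.gene)
    return hits


def probe_detectability(cnv: CnvCall, tables: AnnotationTables) -> tuple[dict, dict]:
    """Count assay probes inside the CNV and flag orthogonal detectability."""
    counts: dict[str, int] = {}
    flags: dict[str, bool] = {}
    chrom = _norm_chrom(cnv.chrom)
    for name in ("aCGH180K", "aCGH1M", "MLPA"):
        trees = tables.probe_sets.get(name) or {}
        tree = trees.get(chrom)
        n = len(tree.overlap(cnv.start, cnv.end)) if tree is not None else 0
        counts[name] = n
        need = MIN_MLPA_PROBES if name == "MLPA" else MIN_ACGH_PROBES
        flags[name] = n >= need
    return counts, flags


def terminal_distance(cnv: CnvCall, grid: TargetGrid) -> tuple[int, int]:
    """Capture targets strictly before / after the call on its chromosome."""
    n = grid.n_targets(cnv.chrom)
    if n == 0:
        raise ValidationError(f"grid has no targets on {cnv.chrom}")
    return cnv.first_target, n - 1 - cnv.last_target


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len(a), overlap/len(b)); both must exceed the threshold."""
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def frequency_annotate(
    cnv: CnvCall,
    batch_calls: dict[str, list[CnvCall]],
    tables: AnnotationTables,
    ro_threshold: float = 0.5,
) -> tuple[float, float]:
    """Fraction of batch samples and max database frequency matching the CNV.

    A record matches when it has the same direction (gain/loss) and
    reciprocal overlap >= ``ro_threshold``.  ``batch_calls`` maps every batch
    sample id (including call-free samples) to its calls.
    """
    n_batch = len(batch_calls)
    carriers = 0
    for sample, calls in batch_calls.items():
        for other in calls:
            if (
                _norm_chrom(other.chrom) == _norm_chrom(cnv.chrom)
                and other.type == cnv.type
                and reciprocal_overlap(cnv.start, cnv.end, other.start, other.end)
                >= ro_threshold
            ):
                carriers += 1
                break
    batch_freq = carriers / n_batch if n_batch else 0.0
    db_freq = 0.0
    for db in (tables.inhouse_db, tables.popsv_db):
        if db is None or db.empty:
            continue
        sub = db[db["chrom"].map(_norm_chrom) == _norm_chrom(cnv.chrom)]
        for _, rec in sub.iterrows():
            if rec["type"] != cnv.type:
                continue
            if reciprocal_overlap(cnv.start, cnv.end, int(rec["start"]),
                                  int(rec["end"])) >= ro_threshold:
                db_freq = max(db_freq, float(rec["frequency"]))
    return batch_freq, db_freq


def size_class(cnv: CnvCall) -> str:
    """Partition by size: < 5 kb exon-level, > 400 kb large, else gene-size."""
    size = cnv.size
    if size > LARGE_MIN:
        return "large"
    if size < EXON_LEVEL_MAX:
        return "exon_level"
    return "gene_size"


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def annotate_calls(
    calls: list[CnvCall],
    grid: TargetGrid,
    tables: AnnotationTables,
    batch_calls: dict[str, list[CnvCall]] | None = None,
    ro_threshold: float = 0.5,
    terminal_targets: int = TERMINAL_TARGETS,
    merge: bool = True,
) -> list[AnnotatedCnv]:
    """Merge one sample's calls and attach the full annotation set."""
    if merge:
        calls = merge_calls(calls, grid)
    out = []
    for c in calls:
        counts, flags = probe_detectability(c, tables)
        pter, qter = terminal_distance(c, grid)
        if batch_calls:
            batch_freq, db_freq = frequency_annotate(c, batch_calls, tables, ro_threshold)
        else:
            _, db_freq = frequency_annotate(c, {}, tables, ro_threshold)
            batch_freq = 0.0
        try:
            band = cytoband_span(c, tables.cytobands)
        except ValidationError:
            band = ""
        out.append(AnnotatedCnv(
            call=c,
            cytoband=band,
            genes=gene_overlap(c, tables),
            probe_counts=counts,
            detectable=flags,
            pter_targets=pter,
            qter_targets=qter,
            terminal=min(pter, qter) <= terminal_targets,
            batch_freq=batch_freq,
            db_freq=db_freq,
            size_class=size_class(c),
        ))
    return out
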