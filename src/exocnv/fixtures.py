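"""Bundled study tables: diagnostic CNVs, cohort records, assay concordance.

Everything here is generated programmatically.  The diagnostic-CNV table
(18 solved cases, 20 CNV segments) carries the published GRCh37
coordinates; the cohort table is a synthetic patient-level stand-in built
to reproduce every published marginal (450 patients, per-category
denominators and positives, 162 total positives of which 18 CNV-diagnosed,
58 VUS, 230 negatives) — it is not the real patient data, which is not
public.  The annotation side tables (gene exon layouts, probe sets, known
pathogenic regions, dosage scores) are synthetic toys constructed only so
that the bundled CNVs annotate and classify the way the diagnostic review
concluded; cytogenetic band boundaries for the bands actually asserted are
the public UCSC values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .depth_model import CnvCall
from .io_formats import AnnotationTables, GeneModel, TargetGrid

# ---------------------------------------------------------------------------
# Diagnostic CNVs (18 solved cases; cases 7 and 13 carry two segments)
# ---------------------------------------------------------------------------

# printed_size is the published (minimal) size string; size_consistent marks
# whether it equals end - start of the printed coordinates (case 3 does not:
# the printed ">4.4 Kb" disagrees with its 3,191 bp coordinate span).
TABLE1 = [
    dict(case=1, phase=2, categories="NDD", library="ES", chrom="22",
         start=44489809, end=51220722, copy_number=1, gene="", exons="",
         printed_size=">6.7 Mb", size_consistent=True, validation="aCGH180k",
         band="22q13.31q13.33", syndrome="Phelan-McDermid (qTer)"),
    dict(case=2, phase=2, categories="NDD", library="ES", chrom="15",
         start=23609491, end=28632839, copy_number=3, gene="", exons="",
         printed_size=">5 Mb", size_consistent=True, validation="aCGH180k",
         band="15q11.2q13.1", syndrome="15q11.2-q13.2 microduplication"),
    dict(case=3, phase=2, categories="blood_immune;NDD", library="ES", chrom="13",
         start=103298645, end=103301836, copy_number=0, gene="TPP2",
         exons="20-22", printed_size=">4.4 Kb", size_consistent=False,
         validation="WGS", band="", syndrome=""),
    dict(case=4, phase=2, categories="NDD;renal", library="ES", chrom="14",
         start=99640489, end=106236323, copy_number=3, gene="", exons="",
         printed_size=">7 Mb", size_consistent=True, validation="aCGH180k",
         band="14q32.2q32.33", syndrome="14q distal duplication (qTer)"),
    dict(case=5, phase=2, categories="renal;NDD", library="ES", chrom="X",
         start=107224311, end=107979574, copy_number=0, gene="", exons="",
         printed_size=">755 kb", size_consistent=True, validation="aCGH180k",
         band="Xq22.3", syndrome=""),
    dict(case=6, phase=2, categories="NDD", library="ES", chrom="2",
         start=237028837, end=242815426, copy_number=1, gene="", exons="",
         printed_size=">5 Mb", size_consistent=True, validation="aCGH180k",
         band="2q37.2q37.3", syndrome="2q37 deletion (qTer)"),
    dict(case=7, phase=2, categories="neurodegeneration", library="ES", chrom="10",
         start=125769666, end=128860040, copy_number=3, gene="", exons="",
         printed_size=">7 Mb", size_consistent=True, validation="aCGH180k",
         band="10q26.13q26.2", syndrome="10q26 deletion syndrome"),
    dict(case=7, phase=2, categories="neurodegeneration", library="ES", chrom="10",
         start=133747956, end=135379033, copy_number=1, gene="", exons="",
         printed_size="", size_consistent=True, validation="aCGH180k",
         band="10q26.3", syndrome="10q26 deletion syndrome"),
    dict(case=8, phase=2, categories="NDD", library="ES", chrom="22",
         start=18834446, end=21414817, copy_number=1, gene="", exons="",
         printed_size=">2.5 Mb", size_consistent=True, validation="aCGH180k",
         band="22q11.21", syndrome="22q11.2 microdeletion"),
    dict(case=9, phase=2, categories="neurodegeneration", library="ES", chrom="7",
         start=92818581, end=94540820, copy_number=1, gene="SGCE", exons="",
         printed_size=">1.7 Mb", size_consistent=True, validation="aCGH180k",
         band="7q21.2q21.3", syndrome=""),
    dict(case=10, phase=2, categories="NDD", library="ES", chrom="17",
         start=1082962, end=1657828, copy_number=3, gene="", exons="",
         printed_size=">574 Kb", size_consistent=True, validation="aCGH180k",
         band="17p13.3", syndrome="17p13.3 microduplication"),
    dict(case=11, phase=2, categories="NDD", library="ES", chrom="1",
         start=146461120, end=147416212, copy_number=3, gene="", exons="",
         printed_size=">955 Kb", size_consistent=True, validation="aCGH180k",
         band="1q21.1q21.2", syndrome="1q21.1 microduplication"),
    dict(case=12, phase=3, categories="hearing_loss", library="TsoE", chrom="15",
         start=43892159, end=43901532, copy_number=1, gene="STRC",
         exons="16-28", printed_size=">9.4 Kb", size_consistent=True,
         validation="MLPA", band="", syndrome="compound het with STRC SNV"),
    dict(case=13, phase=3, categories="neurodegeneration", library="ES", chrom="9",
         start=79827886, end=79828230, copy_number=1, gene="VPS13A",
         exons="8-9", printed_size=">344 bp", size_consistent=True,
         validation="Sanger", band="", syndrome=""),
    dict(case=13, phase=3, categories="neurodegeneration", library="ES", chrom="9",
         start=80018153, end=80018237, copy_number=1, gene="VPS13A",
         exons="69", printed_size=">84 bp", size_consistent=True,
         validation="Sanger", band="", syndrome=""),
    dict(case=14, phase=3, categories="hearing_loss", library="TsoE", chrom="3",
         start=69928286, end=69988332, copy_number=1, gene="MITF",
         exons="1-3", printed_size=">60 Kb", size_consistent=True,
         validation="aCGH1M", band="3p13", syndrome=""),
    dict(case=15, phase=3, categories="metabolic", library="TsoE", chrom="X",
         start=21958944, end=22151741, copy_number=1, gene="PHEX", exons="",
         printed_size=">192 Kb", size_consistent=True, validation="aCGH180k",
         band="Xp22.11", syndrome="hypophosphatemic rickets"),
    dict(case=16, phase=3, categories="NDD", library="TsoE", chrom="X",
         start=99551276, end=99663595, copy_number=1, gene="PCDH19", exons="",
         printed_size=">112 Kb", size_consistent=True, validation="MLPA",
         band="", syndrome="PCDH19 fully deleted"),
    dict(case=17, phase=3, categories="neurodegeneration", library="TsoE", chrom="2",
         start=32352018, end=32353548, copy_number=1, gene="SPAST",
         exons="8-9", printed_size=">1.53 Kb", size_consistent=True,
         validation="MLPA", band="", syndrome=""),
    dict(case=18, phase=3, categories="NDD", library="ES", chrom="15",
         start=22742397, end=28772634, copy_number=4, gene="", exons="",
         printed_size=">6 Mb", size_consistent=True, validation="aCGH180k",
         band="15q11.1q13.1", syndrome="maternal 15q duplication, supernumerary"),
]

# CNVs that escaped the sequencing pipeline and were found by microarray.
TABLE2 = [
    dict(case=19, categories="NDD", library="ES", chrom="17",
         start=2433963, end=2548152, copy_number=1, gene="PAFAH1B1",
         exons="1-2", reason="low_coverage",
         note="first exon untargeted, second poorly covered"),
    dict(case=20, categories="NDD", library="ES", chrom="13",
         start=35615071, end=35697711, copy_number=1, gene="NBEA",
         exons="2-17", reason="gene_not_in_panel",
         note="gene absent from the panel analysed originally"),
    dict(case=21, categories="NDD", library="ES", chrom="14",
         start=105814831, end=106370569, copy_number=1, gene="PACS2",
         exons="", reason="gene_not_in_panel",
         note="gene absent from the panel analysed originally"),
]


def table1_frame() -> pd.DataFrame:
    df = pd.DataFrame(TABLE1)
    df["size_bp"] = df["end"] - df["start"]
    return df


def table2_frame() -> pd.DataFrame:
    return pd.DataFrame(TABLE2)


def table1_calls(grid: TargetGrid | None = None) -> list[tuple[int, CnvCall]]:
    """The diagnostic CNVs as (case, CnvCall), located on the toy grid."""
    grid = grid or toy_grid()
    out = []
    ratio = {0: 0.02, 1: 0.5, 3: 1.5, 4: 2.0}
    for row in TABLE1:
        rows = grid.chrom_rows(row["chrom"])
        starts = grid.df["start"].to_numpy()[rows]
        ends = grid.df["end"].to_numpy()[rows]
        hit = np.flatnonzero((starts < row["end"]) & (ends > row["start"]))
        if hit.size == 0:
            raise AssertionError(f"toy grid misses case {row['case']}")
        call = CnvCall(
            sample=f"case{row['case']}", chrom=row["chrom"],
            first_target=int(hit[0]), last_target=int(hit[-1]),
            start=row["start"], end=row["end"],
            copy_number=row["copy_number"], n_targets=int(hit.size),
            mean_ratio=ratio[row["copy_number"]], quality=50.0,
        )
        out.append((row["case"], call))
    return out


# ---------------------------------------------------------------------------
# Toy annotation tables (synthetic)
# ---------------------------------------------------------------------------

# Public UCSC GRCh37 boundaries for the bands asserted in tests; other
# chromosomes simply have no band table in the toy setting.
CYTOBANDS = [
    ("22", 43500000, 46700000, "q13.31", "gneg"),
    ("22", 46700000, 49400000, "q13.32", "gpos50"),
    ("22", 49400000, 51304566, "q13.33", "gneg"),
    ("3", 69700000, 74100000, "p13", "gneg"),
]


def _exon_run(start: int, n: int, length: int = 90, gap: int = 2000):
    return [(start + i * (length + gap), start + i * (length + gap) + length)
            for i in range(n)]


def toy_gene_models() -> dict[str, GeneModel]:
    """Synthetic exon layouts placing the published affected exons inside
    the published CNV intervals (real exon coordinates are not needed for
    any assertion)."""
    models: dict[str, GeneModel] = {}

    def add(gene, chrom, exons):
        exons = sorted(exons)
        models[gene] = GeneModel(gene, chrom, exons[0][0], exons[-1][1], exons)

    # TPP2: 28 exons; 20-22 inside chr13:103298645-103301836 (copy 0 loss)
    add("TPP2", "13",
        _exon_run(103250000, 19) +                      # exons 1-19 upstream
        [(103299000, 103299100), (103300000, 103300100), (103301000, 103301100)] +
        _exon_run(103305000, 6))                        # exons 23-28 downstream
    # STRC: 29 exons; 16-28 inside chr15:43892159-43901532
    add("STRC", "15",
        _exon_run(43880000, 15, gap=700) +              # exons 1-15 upstream
        _exon_run(43892500, 13, gap=600) +              # exons 16-28 in the CNV
        [(43902000, 43902100)])                         # exon 29 downstream
    # VPS13A: 73 exons; 8-9 in the 344 bp CNV, 69 in the 84 bp CNV
    vps = _exon_run(79790000, 7, gap=5000)              # exons 1-7
    vps += [(79827900, 79827980), (79828100, 79828180)]  # exons 8-9
    vps += _exon_run(79830000, 59, gap=3000)            # exons 10-68
    vps += [(80018170, 80018230)]                       # exon 69
    vps += _exon_run(80020000, 4, gap=3000)             # exons 70-73
    add("VPS13A", "9", vps)
    # MITF: 9 exons; 1-3 inside chr3:69928286-69988332
    add("MITF", "3",
        [(69930000, 69930200), (69950000, 69950200), (69980000, 69980200)] +
        _exon_run(69990000, 6, gap=4000))
    # PHEX: 22 exons, all inside chrX:21958944-22151741 (whole gene)
    add("PHEX", "X", _exon_run(21960000, 22, gap=8000))
    # PCDH19: 6 exons, all inside chrX:99551276-99663595 (whole gene)
    add("PCDH19", "X", _exon_run(99555000, 6, gap=15000))
    # SPAST: 17 exons; 8-9 inside chr2:32352018-32353548
    add("SPAST", "2",
        _exon_run(32330000, 7, gap=2500) +
        [(32352200, 32352300), (32353200, 32353300)] +
        _exon_run(32355000, 8, gap=2500))
    # SGCE: whole gene inside the case 9 deletion
    add("SGCE", "7", _exon_run(93950000, 12, gap=4000))
    # PAFAH1B1: exons 1-2 inside the case 19 region (missed-case narrative)
    add("PAFAH1B1", "17", _exon_run(2496000, 11, gap=5000))
    # NBEA / PACS2: inside the case 20/21 deletions
    add("NBEA", "13", _exon_run(35620000, 16, gap=4000))
    add("PACS2", "14", _exon_run(105830000, 24, gap=4000))
    return models


# Probe-free zones emulating pseudogene-compromised array design (STRC).
ACGH_EXCLUSIONS = [("15", 43880000, 43920000)]
ACGH_180K_SPACING = 13_000
ACGH_1M_SPACING = 2_600


def toy_probe_sets() -> dict[str, dict[str, IntervalTree]]:
    """Regular synthetic probe lattices over the fixture regions.

    180K probes every 13 kb and 1M probes every 2.6 kb (the platforms'
    median spacings), excluding the STRC pseudogene zone; MLPA probes at
    each exon of the genes with available kits.
    """
    t1 = table1_frame()
    spans = {}
    for chrom, sub in t1.groupby("chrom"):
        spans[chrom] = (int(sub["start"].min()) - 100_000,
                        int(sub["end"].max()) + 100_000)
    sets: dict[str, dict[str, IntervalTree]] = {}
    for name, spacing in (("aCGH180K", ACGH_180K_SPACING), ("aCGH1M", ACGH_1M_SPACING)):
        trees: dict[str, IntervalTree] = {}
        for chrom, (lo, hi) in spans.items():
            tree = IntervalTree()
            first = (max(lo, 0) // spacing + 1) * spacing
            for pos in range(first, hi, spacing):
                if any(c == chrom and s <= pos < e for c, s, e in ACGH_EXCLUSIONS):
                    continue
                tree.addi(pos, pos + 60)
            trees[chrom] = tree
        sets[name] = trees
    mlpa: dict[str, IntervalTree] = {}
    models = toy_gene_models()
    for gene in ("PCDH19", "SPAST", "STRC"):  # kits available in the lab
        gm = models[gene]
        tree = mlpa.setdefault(gm.chrom, IntervalTree())
        for s, _ in gm.exons:
            tree.addi(s, s + 60)
    sets["MLPA"] = mlpa
    return sets


KNOWN_REGIONS = [
    # name, chrom, start, end, type — curated recurrent pathogenic regions
    ("22q13_deletion", "22", 44481506, 51186249, "loss"),
    ("15q11q13_duplication", "15", 22765628, 28535051, "gain"),
    ("14q_distal_duplication", "14", 99634561, 107278770, "gain"),
    ("Xq22.3_deletion", "X", 107182490, 108105721, "loss"),
    ("2q37_deletion", "2", 236980552, 243041364, "loss"),
    ("10q26_duplication", "10", 125757754, 128852954, "gain"),
    ("10q26.3_deletion", "10", 133700000, 135434178, "loss"),
    ("22q11.2_deletion", "22", 18894835, 21464119, "loss"),
    ("7q21_deletion", "7", 92776146, 94641008, "loss"),
    ("17p13.3_duplication", "17", 1071072, 1658551, "gain"),
    ("1q21.1_duplication", "1", 146400000, 147900000, "gain"),
]


def known_regions_frame() -> pd.DataFrame:
    return pd.DataFrame(KNOWN_REGIONS,
                        columns=["name", "chrom", "start", "end", "type"])


GENE_DOSAGE = [
    # gene, hi_score, ts_score, domino, disease_flag, pseudogene_flag
    ("TPP2", 1, 0, 0.10, 1, 0),
    ("STRC", 1, 0, 0.05, 1, 1),
    ("VPS13A", 1, 0, 0.08, 1, 0),
    ("MITF", 3, 0, 0.92, 1, 0),
    ("PHEX", 3, 0, 0.95, 1, 0),
    ("PCDH19", 3, 0, 0.90, 1, 0),
    ("SPAST", 3, 0, 0.97, 1, 0),
    ("SGCE", 3, 0, 0.91, 1, 0),
    ("PAFAH1B1", 3, 0, 0.98, 1, 0),
    ("NBEA", 1, 0, 0.85, 1, 0),
    ("PACS2", 1, 0, 0.88, 1, 0),
]


def gene_dosage_frame() -> pd.DataFrame:
    return pd.DataFrame(GENE_DOSAGE, columns=[
        "gene", "hi_score", "ts_score", "domino", "disease_flag",
        "pseudogene_flag"])


PANELS = {
    "NDD": {"PCDH19", "PAFAH1B1", "NBEA", "PACS2"},
    "neurodegeneration": {"VPS13A", "SPAST", "SGCE"},
    "hearing_loss": {"STRC", "MITF"},
    "metabolic": {"PHEX"},
    "blood_immune": {"TPP2"},
    "renal": set(),
}


def toy_annotation_tables() -> AnnotationTables:
    return AnnotationTables(
        cytobands=pd.DataFrame(CYTOBANDS,
                               columns=["chrom", "start", "end", "band", "stain"]),
        gene_model=toy_gene_models(),
        probe_sets=toy_probe_sets(),
        panels={k: set(v) for k, v in PANELS.items()},
        gene_dosage=gene_dosage_frame(),
    )


def toy_grid(lattice_spacing: int = 50_000, target_len: int = 120) -> TargetGrid:
    """Capture-target lattice covering the fixture CNVs plus toy gene exons."""
    rows = []
    for gene, gm in toy_gene_models().items():
        for i, (s, e) in enumerate(gm.exons, 1):
            rows.append((gm.chrom, s, e, gene, i))
    t1 = table1_frame()
    for chrom, sub in t1.groupby("chrom"):
        lo = int(sub["start"].min()) - 100_000
        hi = int(sub["end"].max()) + 100_000
        first = (max(lo, 0) // lattice_spacing + 1) * lattice_spacing
        for pos in range(first, hi, lattice_spacing):
            rows.append((chrom, pos, pos + target_len, "", None))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "exon_index"])
    df = df.drop_duplicates(subset=["chrom", "start", "end", "gene"])
    return TargetGrid(df)


def phenotype_genes_for(categories: str | list[str]) -> set[str]:
    if isinstance(categories, str):
        categories = categories.split(";")
    out: set[str] = set()
    for c in categories:
        out |= PANELS.get(c, set())
    return out


# ---------------------------------------------------------------------------
# Cohort records
# ---------------------------------------------------------------------------

# Per-category cohort size and positives: (category, n, snv_positive_singles)
# CNV-diagnosed patients enter through the diagnostic-CNV table below.
_CATEGORY_PLAN = [
    ("NDD", 227, 77),
    ("neurodegeneration", 63, 13),
    ("renal", 40, 12),
    ("heart", 35, 13),
    ("connective", 20, 6),
    ("vision", 19, 12),
    ("hearing_loss", 17, 4),
    ("neuromuscular", 14, 4),
    ("mitochondrial", 12, 1),
    ("blood_immune", 11, 0),
    ("metabolic", 10, 2),
    ("pulmonary_fibrosis", 7, 0),
    ("diverse", 20, 0),
]

#: dual-category patients among the non-positives, to reconcile per-category
#: denominators with the cohort size (42 patients analysed on both the
#: neurodevelopmental and neurodegeneration panels).
_N_DUAL_NEGATIVE = 42
_N_VUS_CNV = 3
_N_VUS_SNV = 55


def cohort_records() -> list:
    """Synthetic patient-level cohort reproducing the published marginals."""
    from .cohort_report import CohortRecord

    records: list[CohortRecord] = []
    # 1) CNV-diagnosed patients (one per solved case; case 12 carries both a
    #    CNV and an SNV in the same gene).
    seen = set()
    for row in TABLE1:
        if row["case"] in seen:
            continue
        seen.add(row["case"])
        outcome = "positive_both" if row["case"] == 12 else "positive_cnv"
        records.append(CohortRecord(
            patient_id=f"P-CNV{row['case']:02d}",
            categories=tuple(row["categories"].split(";")),
            outcome=outcome,
            acgh_status="validation" if row["phase"] == 2 else "none",
        ))
    # 2) SNV-diagnosed patients, single category.
    for cat, _, n_snv in _CATEGORY_PLAN:
        for i in range(n_snv):
            records.append(CohortRecord(f"P-{cat[:4].upper()}-S{i:03d}",
                                        (cat,), "positive_snv"))
    # 3) Non-positive patients: dual-panel patients first, then singles.
    nonpos: list[CohortRecord] = []
    for i in range(_N_DUAL_NEGATIVE):
        nonpos.append(CohortRecord(f"P-DUAL-{i:03d}",
                                   ("NDD", "neurodegeneration"), "negative"))
    cnv_by_cat: dict[str, int] = {}
    for r in records:
        if r.outcome in ("positive_cnv", "positive_both"):
            for c in r.categories:
                cnv_by_cat[c] = cnv_by_cat.get(c, 0) + 1
    for cat, n_total, n_snv in _CATEGORY_PLAN:
        n_nonpos = n_total - n_snv - cnv_by_cat.get(cat, 0)
        if cat == "NDD" or cat == "neurodegeneration":
            n_nonpos -= _N_DUAL_NEGATIVE
        for i in range(n_nonpos):
            nonpos.append(CohortRecord(f"P-{cat[:4].upper()}-N{i:03d}",
                                       (cat,), "negative"))
    # 4) Recode the first non-positives as VUS carriers.
    for i, rec in enumerate(nonpos):
        if i < _N_VUS_CNV:
            rec.outcome = "vus_cnv"
        elif i < _N_VUS_CNV + _N_VUS_SNV:
            rec.outcome = "vus_snv"
    records.extend(nonpos)
    # 5) Microarray history: 87 analysed before sequencing, 15 used for
    #    validation (11 phase-2 CNV cases + 4 VUS work-ups), 18 after a
    #    negative result.
    n_validation = sum(r.acgh_status == "validation" for r in records)
    for rec in records:
        if n_validation >= 15:
            break
        if rec.outcome == "vus_cnv" and rec.acgh_status == "none":
            rec.acgh_status = "validation"
            n_validation += 1
    for rec in records:
        if n_validation >= 15:
            break
        if rec.outcome == "vus_snv" and rec.acgh_status == "none":
            rec.acgh_status = "validation"
            n_validation += 1
    n_before = 0
    for rec in records:
        if n_before >= 87:
            break
        if rec.acgh_status == "none":
            rec.acgh_status = "before_ngs"
            n_before += 1
    n_after = 0
    for rec in reversed(records):
        if n_after >= 18:
            break
        if rec.acgh_status == "none" and rec.outcome == "negative":
            rec.acgh_status = "after_ngs"
            n_after += 1
    return records


# ---------------------------------------------------------------------------
# Microarray-VUS concordance records
# ---------------------------------------------------------------------------

def acgh_vus_frame() -> pd.DataFrame:
    """24 microarray VUS CNVs re-examined in sequencing data: 19 detected,
    4 in regions without capture targets, 1 a batch/population polymorphism."""
    rows = []
    for i in range(1, 25):
        rows.append({
            "cnv_id": f"V{i:02d}",
            "has_ngs_targets": i > 4,          # V01-V04: intronic/intergenic
            "polymorphic_in_batch": i == 5,    # V05: polymorphic duplication
            "acgh_timing": "before_ngs" if i <= 22 else "validation",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def make_paper_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write every bundled table under ``outdir``; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .cohort_report import records_to_frame

    paths: dict[str, Path] = {}

    def _save(name: str, df: pd.DataFrame, **kw):
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, **kw)
        paths[name] = p

    _save("table1_cnvs.tsv", table1_frame())
    _save("table2_missed.tsv", table2_frame())
    _save("cohort.tsv", records_to_frame(cohort_records()))
    _save("acgh_vus.tsv", acgh_vus_frame())
    _save("known_regions.tsv", known_regions_frame())
    _save("gene_dosage.tsv", gene_dosage_frame())
    _save("panels.tsv", pd.DataFrame(
        [(panel, g) for panel, genes in PANELS.items() for g in sorted(genes)],
        columns=["panel", "gene"]))

    p = outdir / "cytobands_toy.txt"
    pd.DataFrame(CYTOBANDS).assign(chrom=lambda d: "chr" + d[0]).to_csv(
        p, sep="\t", header=False, index=False,
        columns=["chrom", 1, 2, 3, 4])
    paths["cytobands_toy.txt"] = p

    p = outdir / "genes_toy_refflat.txt"
    with open(p, "w") as fh:
        for gene, gm in toy_gene_models().items():
            starts = ",".join(str(s) for s, _ in gm.exons) + ","
            ends = ",".join(str(e) for _, e in gm.exons) + ","
            fh.write("\t".join([
                gene, f"{gene}-tx1", gm.chrom, "+", str(gm.tx_start),
                str(gm.tx_end), str(gm.tx_start), str(gm.tx_end),
                str(len(gm.exons)), starts, ends]) + "\n")
    paths["genes_toy_refflat.txt"] = p

    for name, fname in (("aCGH180K", "probes_acgh180k_toy.bed"),
                        ("aCGH1M", "probes_acgh1m_toy.bed"),
                        ("MLPA", "probes_mlpa_toy.bed")):
        p = outdir / fname
        with open(p, "w") as fh:
            for chrom, tree in sorted(toy_probe_sets()[name].items()):
                for iv in sorted(tree):
                    fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\n")
        paths[fname] = p

    p = outdir / "targets_toy.bed"
    grid = toy_grid()
    with open(p, "w") as fh:
        for _, r in grid.df.iterrows():
            exon = "" if pd.isna(r["exon_index"]) else int(r["exon_index"])
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['gene']}\t{exon}\n")
    paths["targets_toy.bed"] = p
    return paths
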