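"""Readers and writers for the tables and standard formats the pipeline touches.

All genomic intervals are held internally as 0-based, half-open
``[start, end)`` coordinates, so the size of an interval is always
``end - start``.  VCF output converts to 1-based positions as the standard
requires.  Every reader validates rather than silently coercing: malformed
lines raise :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Default number of samples sequenced together, per capture design.
BATCH_SIZES = {"ES": 32, "TsoE": 8}

#: ClinGen dosage-sensitivity score vocabulary (0-3 plus the 30 "autosomal
#: recessive" and 40 "dosage sensitivity unlikely" codes).
CLINGEN_SCORES = {0, 1, 2, 3, 30, 40}


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def _norm_chrom(chrom: str) -> str:
    """Normalise chromosome names to the bare form (``chr1`` -> ``1``)."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# Capture-target grid
# ---------------------------------------------------------------------------

class TargetGrid:
    """Ordered capture targets: the coordinate lattice for all depth math.

    Targets are sorted by ``(chrom, start, end)`` and numbered densely
    ``0..n-1`` within each chromosome (``target_id``); target-count distances
    to the chromosome termini (pTer/qTer) are defined on this lattice.
    """

    COLUMNS = ["chrom", "start", "end", "gene", "exon_index", "target_id"]

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValidationError(f"target table needs columns {sorted(required)}")
        df = df.copy()
        if "gene" not in df:
            df["gene"] = ""
        if "exon_index" not in df:
            df["exon_index"] = pd.NA
        df["gene"] = df["gene"].fillna("")
        bad = df["end"] <= df["start"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"degenerate target (end <= start) at row {i}: "
                f"{df.iloc[i]['chrom']}:{df.iloc[i]['start']}-{df.iloc[i]['end']}"
            )
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "start", "end", "gene"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(f"duplicate target row: {df.iloc[i].to_dict()}")
        df["target_id"] = df.groupby("chrom", sort=False).cumcount()
        self.df = df[self.COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, TargetGrid) and self.df.equals(other.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_rows(self, chrom: str) -> np.ndarray:
        """Global row indices (count-matrix columns) of one chromosome."""
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def n_targets(self, chrom: str) -> int:
        return int((self.df["chrom"] == chrom).sum())


def read_targets(path: str | Path) -> TargetGrid:
    """Read capture targets from BED (columns 4/5: gene symbol, exon index)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end <= start ({start}, {end})")
            gene = fields[3] if len(fields) > 3 else ""
            exon = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    exon = int(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: exon index not an integer") from exc
                if exon < 1:
                    raise ValidationError(f"{path}:{lineno}: exon index must be >=1")
            rows.append((fields[0], start, end, gene, exon))
    if not rows:
        raise ParseError(f"{path}: no targets found")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "exon_index"])
    return TargetGrid(df)


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def count_reads(path: str | Path, grid: TargetGrid, min_mapq: int = 20) -> np.ndarray:
    """Count reads per capture target for one sample.

    A read is assigned to the target containing its leftmost aligned base
    (half-open: a read starting exactly at ``end`` is outside).  Unmapped,
    secondary, supplementary and duplicate-flagged reads and reads below
    ``min_mapq`` are skipped.  Accepts coordinate-sorted indexed BAM/CRAM or
    plain SAM (streamed).
    """
    import pysam

    path = str(path)
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as af:
        file_chroms = {_norm_chrom(r): r for r in af.references or ()}
        grid_chroms = grid.chroms
        unmatched = [c for c in grid_chroms if _norm_chrom(c) not in file_chroms]
        if unmatched and len(unmatched) == len(grid_chroms):
            raise ValidationError(
                "no grid chromosome matches the alignment file; unmatched: "
                + ", ".join(unmatched)
            )
        counts = np.zeros(len(grid), dtype=np.int64)
        use_fetch = mode == "rb"
        if use_fetch:
            try:
                af.check_index()
            except (ValueError, AttributeError) as exc:
                raise ValidationError(
                    f"{path} has no index; create one with 'samtools index'"
                ) from exc
        starts = grid.df["start"].to_numpy()
        ends = grid.df["end"].to_numpy()

        def _tally(read, rows, row_starts, row_ends):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < min_mapq
            ):
                return
            pos = read.reference_start
            j = np.searchsorted(row_starts, pos, side="right") - 1
            if j >= 0 and pos < row_ends[j]:
                counts[rows[j]] += 1

        for chrom in grid_chroms:
            ref = file_chroms.get(_norm_chrom(chrom))
            if ref is None:
                logger.warning("chromosome %s absent from %s; counts left 0", chrom, path)
                continue
            rows = grid.chrom_rows(chrom)
            rs, re_ = starts[rows], ends[rows]
            if use_fetch:
                for read in af.fetch(ref, int(rs.min()), int(re_.max())):
                    _tally(read, rows, rs, re_)
        if not use_fetch:
            by_ref = {
                _norm_chrom(c): (grid.chrom_rows(c),) for c in grid_chroms
            }
            for read in af:
                if read.is_unmapped:
                    continue
                entry = by_ref.get(_norm_chrom(read.reference_name))
                if entry is None:
                    continue
                rows = entry[0]
                _tally(read, rows, starts[rows], ends[rows])
    return counts


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Per-sample per-target read counts for one sequencing batch."""

    sample_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_targets), non-negative ints
    library_kind: str = "ES"
    override_batch_size: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.sample_ids):
            raise ValidationError("counts must be (n_samples, n_targets)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            s, t = map(int, np.argwhere(self.counts < 0)[0])
            raise ValidationError(
                f"negative count at sample {self.sample_ids[s]!r}, target column {t}"
            )
        if self.library_kind not in BATCH_SIZES:
            raise ValidationError(f"library_kind must be one of {sorted(BATCH_SIZES)}")
        expected = BATCH_SIZES[self.library_kind]
        if not self.override_batch_size and len(self.sample_ids) != expected:
            raise ValidationError(
                f"{self.library_kind} batches have {expected} samples, got "
                f"{len(self.sample_ids)}; pass override_batch_size=True to allow"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_targets(self) -> int:
        return int(self.counts.shape[1])

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.counts[self.sample_ids.index(sample_id)]
        except ValueError as exc:
            raise KeyError(f"sample {sample_id!r} not in batch") from exc

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.sample_ids == other.sample_ids
            and self.library_kind == other.library_kind
            and np.array_equal(self.counts, other.counts)
        )


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV: header = target columns, one row per sample."""
    df = pd.DataFrame(
        matrix.counts,
        index=pd.Index(matrix.sample_ids, name="sample"),
        columns=[f"t{i}" for i in range(matrix.n_targets)],
    )
    with open(path, "w") as fh:
        fh.write(f"#library_kind={matrix.library_kind}\n")
        df.to_csv(fh, sep="\t")


def read_count_matrix(path: str | Path, library_kind: str | None = None) -> CountMatrix:
    kind = library_kind
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#library_kind="):
            kind = kind or first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ParseError(f"{path}: empty count matrix")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df[~df.map(lambda v: isinstance(v, (int, np.integer)))].stack()
        cell = bad.index[0]
        raise ValidationError(f"{path}: non-integer count at {cell}")
    if np.any(arr != np.floor(arr)):
        s, t = map(int, np.argwhere(arr != np.floor(arr))[0])
        raise ValidationError(f"{path}: non-integer count at row {df.index[s]}, col {df.columns[t]}")
    if np.any(arr < 0):
        s, t = map(int, np.argwhere(arr < 0)[0])
        raise ValidationError(f"{path}: negative count at row {df.index[s]}, col {df.columns[t]}")
    return CountMatrix(
        sample_ids=[str(s) for s in df.index],
        counts=arr.astype(np.int64),
        library_kind=kind or "ES",
        override_batch_size=True,
    )


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene: transcript span plus ordered exon intervals (0-based)."""

    gene: str
    chrom: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]  # sorted (start, end)


@dataclass
class AnnotationTables:
    """Everything the annotator and classifier consult, pre-indexed."""

    cytobands: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "band", "stain"]))
    gene_model: dict[str, GeneModel] = field(default_factory=dict)
    probe_sets: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)
    panels: dict[str, set[str]] = field(default_factory=dict)
    inhouse_db: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "type", "frequency"]))
    popsv_db: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "type", "frequency"]))
    gene_dosage: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene", "hi_score", "ts_score", "domino", "disease_flag",
                 "pseudogene_flag"]))

    def genes_on(self, chrom: str) -> list[GeneModel]:
        c = _norm_chrom(chrom)
        return [g for g in self.gene_model.values() if _norm_chrom(g.chrom) == c]

    def dosage_for(self, gene: str) -> dict | None:
        df = self.gene_dosage
        hit = df[df["gene"] == gene]
        if hit.empty:
            return None
        return hit.iloc[0].to_dict()


def read_cytobands(path: str | Path) -> pd.DataFrame:
    """Read a UCSC cytoBand.txt table (chrom, start, end, band, stain)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str, "stain": str},
    )
    if df[["start", "end"]].isna().any().any():
        raise ParseError(f"{path}: missing coordinates in cytoband table")
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    for chrom, sub in df.groupby("chrom"):
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValidationError(f"{path}: overlapping bands on {chrom}")
    return df


def read_refflat(path: str | Path) -> dict[str, GeneModel]:
    """Read a refFlat-style gene table into per-gene exon models.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds.  Multiple transcripts of one gene are
    collapsed to the union span with the transcript of most exons kept.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise ParseError(f"{path}:{lineno}: expected 11 refFlat columns")
            gene, chrom = f[0], f[2]
            try:
                tx_start, tx_end = int(f[4]), int(f[5])
                starts = [int(x) for x in f[9].rstrip(",").split(",")]
                ends = [int(x) for x in f[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if len(starts) != len(ends):
                raise ParseError(f"{path}:{lineno}: exonStarts/exonEnds length mismatch")
            exons = sorted(zip(starts, ends))
            prev = models.get(gene)
            if prev is None or len(exons) > len(prev.exons):
                span = (
                    min(tx_start, prev.tx_start) if prev else tx_start,
                    max(tx_end, prev.tx_end) if prev else tx_end,
                )
                models[gene] = GeneModel(gene, chrom, span[0], span[1], exons)
            else:
                prev.tx_start = min(prev.tx_start, tx_start)
                prev.tx_end = max(prev.tx_end, tx_end)
    return models


def read_probe_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a probe set BED into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                end = start + 1  # point probes given as zero-length
            trees.setdefault(_norm_chrom(f[0]), IntervalTree()).addi(start, end)
    return trees


def read_panels(path: str | Path) -> dict[str, set[str]]:
    """Read gene panels from TSV: columns panel, gene (one gene per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"panel", "gene"}.issubset(df.columns):
        raise ParseError(f"{path}: panel table needs columns panel, gene")
    return {name: set(sub["gene"]) for name, sub in df.groupby("panel")}


def read_frequency_db(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "type": str})
    need = {"chrom", "start", "end", "type", "frequency"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: frequency table needs columns {sorted(need)}")
    if ((df["frequency"] < 0) | (df["frequency"] > 1)).any():
        raise ValidationError(f"{path}: frequency outside [0,1]")
    return df


def read_gene_dosage(path: str | Path) -> pd.DataFrame:
    """Read the per-gene dosage annotation table.

    Columns: gene, hi_score, ts_score (ClinGen vocabulary), domino (in [0,1]),
    disease_flag, pseudogene_flag (0/1).
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ParseError(f"{path}: dosage table needs a gene column")
    for col in ("hi_score", "ts_score"):
        if col in df:
            vals = df[col].dropna()
            bad = ~vals.isin(CLINGEN_SCORES)
            if bad.any():
                raise ValidationError(
                    f"{path}: {col} value {vals[bad].iloc[0]} outside ClinGen "
                    f"vocabulary {sorted(CLINGEN_SCORES)}"
                )
    if "domino" in df:
        vals = df["domino"].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"{path}: DOMINO score outside [0,1]")
    for col in ("disease_flag", "pseudogene_flag"):
        if col not in df:
            df[col] = 0
    return df


def read_annotation_tables(
    cytobands: str | Path | None = None,
    genes: str | Path | None = None,
    probes_180k: str | Path | None = None,
    probes_1m: str | Path | None = None,
    probes_mlpa: str | Path | None = None,
    panels: str | Path | None = None,
    inhouse: str | Path | None = None,
    popsv: str | Path | None = None,
    dosage: str | Path | None = None,
) -> AnnotationTables:
    """Assemble :class:`AnnotationTables`; absent optional tables stay empty."""
    tables = AnnotationTables()
    if cytobands:
        tables.cytobands = read_cytobands(cytobands)
    probe_paths = {"aCGH180K": probes_180k, "aCGH1M": probes_1m, "MLPA": probes_mlpa}
    for name, p in probe_paths.items():
        if p:
            tables.probe_sets[name] = read_probe_bed(p)
        else:
            logger.warning("probe set %s not provided; detectability will be False", name)
            tables.probe_sets[name] = {}
    if genes:
        tables.gene_model = read_refflat(genes)
    if panels:
        tables.panels = read_panels(panels)
    if inhouse:
        tables.inhouse_db = read_frequency_db(inhouse)
    if popsv:
        tables.popsv_db = read_frequency_db(popsv)
    if dosage:
        tables.gene_dosage = read_gene_dosage(dosage)
    return tables


# ---------------------------------------------------------------------------
# Call output
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "sample", "chrom", "start", "end", "type", "copy_number", "n_targets",
    "first_target", "last_target", "mean_ratio", "quality", "mosaic_fraction",
]


def calls_to_frame(calls: Sequence) -> pd.DataFrame:
    rows = []
    for c in calls:
        base = getattr(c, "call", c)  # AnnotatedCnv wraps a CnvCall
        row = {k: getattr(base, k) for k in CALL_COLUMNS}
        for extra in (
            "cytoband", "size_class", "batch_freq", "db_freq",
            "pter_targets", "qter_targets", "terminal",
        ):
            if hasattr(c, extra):
                row[extra] = getattr(c, extra)
        if hasattr(c, "genes"):
            row["genes"] = ";".join(
                f"{g.gene}:{g.n_exons}" + ("*" if g.whole_gene else "")
                for g in c.genes
            )
        if hasattr(c, "probe_counts"):
            for k, v in c.probe_counts.items():
                row[f"probes_{k}"] = v
            for k, v in c.detectable.items():
                row[f"detectable_{k}"] = v
        if hasattr(c, "classification"):
            row["classification"] = c.classification
            row["in_panel"] = c.in_panel
            row["evidence"] = "|".join(r for r, _ in c.evidence)
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls(calls: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write calls as TSV (stable documented columns) or VCF 4.2.

    VCF records carry SVTYPE (DEL/DUP), END, CN and, for mosaic events, a
    MOSAIC fraction; positions are converted to 1-based.
    """
    if format == "tsv":
        df = calls_to_frame(calls)
        if df.empty:
            df = pd.DataFrame(columns=CALL_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
            fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
            fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
            fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
            fh.write('##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy number">\n')
            fh.write('##INFO=<ID=MOSAIC,Number=1,Type=Float,Description="Mosaic cell fraction">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = sorted({getattr(getattr(c, "call", c), "sample") for c in calls})
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples or ["sample"]) + "\n"
            )
            for c in calls:
                base = getattr(c, "call", c)
                svtype = "DEL" if base.copy_number < 2 else "DUP"
                info = f"SVTYPE={svtype};END={base.end};CN={base.copy_number}"
                f = base.mosaic_fraction
                if f is not None and f < 0.95:
                    info += f";MOSAIC={f:.3f}"
                gts = ["./."] * max(len(samples), 1)
                if samples:
                    gts[samples.index(base.sample)] = "0/1" if base.copy_number in (1, 3) else "1/1"
                fh.write(
                    f"{base.chrom}\t{base.start + 1}\t.\tN\t<{svtype}>\t"
                    f"{base.quality:.1f}\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
                )
    else:
        raise ValueError(f"unknown call output format {format!r}")


def read_calls(path: str | Path):
    """Read a calls TSV back into :class:`~exocnv.depth_model.CnvCall` objects."""
    from .depth_model import CnvCall

    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, row in df.iterrows():
        f = row.get("mosaic_fraction")
        calls.append(CnvCall(
            sample=str(row["sample"]), chrom=str(row["chrom"]),
            first_target=int(row["first_target"]), last_target=int(row["last_target"]),
            start=int(row["start"]), end=int(row["end"]),
            copy_number=int(row["copy_number"]), n_targets=int(row["n_targets"]),
            mean_ratio=float(row["mean_ratio"]), quality=float(row["quality"]),
            mosaic_fraction=None if pd.isna(f) else float(f),
        ))
    return calls
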