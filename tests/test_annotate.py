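"""Annotation: merging, cytobands, gene/probe overlap, frequency, size class."""

import itertools

import pandas as pd
import pytest

from exocnv.annotate import (
    EXON_LEVEL_MAX,
    LARGE_MIN,
    MIN_ACGH_PROBES,
    MIN_MLPA_PROBES,
    annotate_calls,
    cytoband_span,
    frequency_annotate,
    gene_overlap,
    merge_calls,
    probe_detectability,
    reciprocal_overlap,
    size_class,
    terminal_distance,
)
from exocnv.io_formats import AnnotationTables, ValidationError

from conftest import make_call


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

class TestMergeCalls:
    def test_gap_of_two_targets_merges(self, small_grid):
        a = make_call(first=0, last=1, copy_number=1)
        b = make_call(first=4, last=5, copy_number=1)  # targets 2,3 skipped
        merged = merge_calls([a, b], small_grid)
        assert len(merged) == 1
        m = merged[0]
        assert (m.first_target, m.last_target) == (0, 5)
        assert (m.start, m.end) == (a.start, b.end)
        assert m.n_targets == 4  # called targets only

    def test_gap_of_three_targets_does_not_merge(self, small_grid):
        a = make_call(first=0, last=1, copy_number=1)
        b = make_call(first=5, last=6, copy_number=1)  # targets 2,3,4 skipped
        assert len(merge_calls([a, b], small_grid)) == 2

    def test_different_ploidy_never_merges(self, small_grid):
        a = make_call(first=0, last=1, copy_number=1)
        b = make_call(first=3, last=4, copy_number=0)
        assert len(merge_calls([a, b], small_grid)) == 2

    def test_chain_merges_through_fixpoint(self, small_grid):
        calls = [make_call(first=i, last=i, copy_number=3) for i in (0, 2, 4, 6)]
        merged = merge_calls(calls, small_grid)
        assert len(merged) == 1
        assert (merged[0].first_target, merged[0].last_target) == (0, 6)

    def test_order_invariant_and_idempotent(self, small_grid):
        calls = [
            make_call(first=0, last=1, copy_number=1),
            make_call(first=3, last=4, copy_number=1),
            make_call(first=8, last=9, copy_number=3),
        ]
        expected = merge_calls(calls, small_grid)
        for perm in itertools.permutations(calls):
            assert merge_calls(list(perm), small_grid) == expected
        assert merge_calls(expected, small_grid) == expected

    def test_merged_ratio_is_weighted_and_quality_max(self, small_grid):
        a = make_call(first=0, last=2, copy_number=1, mean_ratio=0.4, quality=10)
        b = make_call(first=4, last=4, copy_number=1, mean_ratio=0.8, quality=30)
        m = merge_calls([a, b], small_grid)[0]
        assert m.mean_ratio == pytest.approx((0.4 * 3 + 0.8 * 1) / 4)
        assert m.quality == 30

    def test_overlapping_different_ploidy_is_an_error(self, small_grid):
        a = make_call(first=0, last=3, copy_number=1)
        b = make_call(first=2, last=5, copy_number=3)
        with pytest.raises(ValidationError, match="overlapping"):
            merge_calls([a, b], small_grid)

    def test_different_chromosomes_untouched(self, small_grid):
        a = make_call(first=0, last=1, copy_number=1, chrom="1")
        b = make_call(first=3, last=4, copy_number=1, chrom="2")
        assert len(merge_calls([a, b], small_grid)) == 2


# ---------------------------------------------------------------------------
# Cytobands
# ---------------------------------------------------------------------------

class TestCytobandSpan:
    def test_multi_band_span(self, study_tables):
        cnv = make_call(chrom="22", start=44489809, end=51220722,
                        first=0, last=10)
        assert cytoband_span(cnv, study_tables.cytobands) == "22q13.31q13.33"

    def test_single_band(self, study_tables):
        cnv = make_call(chrom="3", start=69928286, end=69988332,
                        first=0, last=3)
        assert cytoband_span(cnv, study_tables.cytobands) == "3p13"

    def test_outside_coverage_raises(self, study_tables):
        cnv = make_call(chrom="9", start=100, end=2000, first=0, last=1)
        with pytest.raises(ValidationError, match="cytoband"):
            cytoband_span(cnv, study_tables.cytobands)

    def test_chr_prefix_normalised(self, study_tables):
        cnv = make_call(chrom="chr3", start=69928286, end=69988332,
                        first=0, last=3)
        assert cytoband_span(cnv, study_tables.cytobands) == "3p13"


# ---------------------------------------------------------------------------
# Gene overlap
# ---------------------------------------------------------------------------

class TestGeneOverlap:
    def test_partial_exon_hit(self, study_tables):
        # the published VPS13A exon 8-9 deletion
        cnv = make_call(chrom="9", start=79827886, end=79828230,
                        first=0, last=1, copy_number=1)
        hits = gene_overlap(cnv, study_tables)
        assert [h.gene for h in hits] == ["VPS13A"]
        assert hits[0].n_exons == 2
        assert not hits[0].whole_gene
        assert hits[0].dosage["disease_flag"] == 1

    def test_whole_gene_hit(self, study_tables):
        cnv = make_call(chrom="X", start=99551276, end=99663595,
                        first=0, last=5, copy_number=1)
        hits = gene_overlap(cnv, study_tables)
        assert [h.gene for h in hits] == ["PCDH19"]
        assert hits[0].whole_gene

    def test_intronic_only_flagged(self, study_tables):
        # between SPAST exons 9 (ends 32353300) and 10 (starts 32355000)
        cnv = make_call(chrom="2", start=32353400, end=32354900,
                        first=0, last=0, copy_number=1)
        hits = gene_overlap(cnv, study_tables)
        assert hits and hits[0].intronic_only and hits[0].n_exons == 0

    def test_pseudogene_flag_propagates(self, study_tables):
        cnv = make_call(chrom="15", start=43892159, end=43901532,
                        first=0, last=12, copy_number=1)
        hits = gene_overlap(cnv, study_tables)
        strc = next(h for h in hits if h.gene == "STRC")
        assert strc.pseudogene_flag


# ---------------------------------------------------------------------------
# Probe detectability
# ---------------------------------------------------------------------------

class TestProbeDetectability:
    def test_thresholds_are_3_for_acgh_and_2_for_mlpa(self):
        assert MIN_ACGH_PROBES == 3 and MIN_MLPA_PROBES == 2

    @staticmethod
    def _tables_with_probes(n_acgh, n_mlpa):
        from intervaltree import IntervalTree

        acgh = IntervalTree()
        for i in range(n_acgh):
            acgh.addi(1000 + i * 100, 1060 + i * 100)
        mlpa = IntervalTree()
        for i in range(n_mlpa):
            mlpa.addi(1010 + i * 100, 1070 + i * 100)
        return AnnotationTables(probe_sets={
            "aCGH180K": {"1": acgh}, "aCGH1M": {}, "MLPA": {"1": mlpa},
        })

    def test_acgh_boundary_two_vs_three(self):
        cnv = make_call(chrom="1", start=900, end=2500, first=0, last=1)
        counts, flags = probe_detectability(
            cnv, self._tables_with_probes(n_acgh=2, n_mlpa=0))
        assert counts["aCGH180K"] == 2 and not flags["aCGH180K"]
        counts, flags = probe_detectability(
            cnv, self._tables_with_probes(n_acgh=3, n_mlpa=0))
        assert counts["aCGH180K"] == 3 and flags["aCGH180K"]

    def test_mlpa_boundary_one_vs_two(self):
        cnv = make_call(chrom="1", start=900, end=2500, first=0, last=1)
        counts, flags = probe_detectability(
            cnv, self._tables_with_probes(n_acgh=0, n_mlpa=1))
        assert counts["MLPA"] == 1 and not flags["MLPA"]
        counts, flags = probe_detectability(
            cnv, self._tables_with_probes(n_acgh=0, n_mlpa=2))
        assert flags["MLPA"]

    def test_missing_probe_set_counts_zero(self):
        cnv = make_call(chrom="1", start=900, end=2500, first=0, last=1)
        counts, flags = probe_detectability(cnv, AnnotationTables())
        assert counts == {"aCGH180K": 0, "aCGH1M": 0, "MLPA": 0}
        assert not any(flags.values())

    def test_strc_deletion_invisible_to_arrays_but_mlpa_detectable(self, study_tables):
        # probes excluded over the pseudogene zone; MLPA kit targets each exon
        cnv = make_call(chrom="15", start=43892159, end=43901532,
                        first=0, last=12, copy_number=1)
        counts, flags = probe_detectability(cnv, study_tables)
        assert counts["aCGH180K"] == 0 and counts["aCGH1M"] == 0
        assert counts["MLPA"] >= 2 and flags["MLPA"]


# ---------------------------------------------------------------------------
# Terminal distance, reciprocal overlap, frequency, size class
# ---------------------------------------------------------------------------

class TestTerminalDistance:
    def test_counts_targets_on_both_sides(self, small_grid):
        cnv = make_call(first=2, last=4)
        assert terminal_distance(cnv, small_grid) == (2, 5)

    def test_terminal_call(self, small_grid):
        cnv = make_call(first=7, last=9)
        assert terminal_distance(cnv, small_grid) == (7, 0)

    def test_unknown_chromosome(self, small_grid):
        cnv = make_call(chrom="99")
        with pytest.raises(ValidationError):
            terminal_distance(cnv, small_grid)


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        assert reciprocal_overlap(100, 200, 100, 200) == 1.0

    def test_disjoint(self):
        assert reciprocal_overlap(100, 200, 200, 300) == 0.0

    def test_takes_the_minimum_side(self):
        # a fully contains b, but b is half of a
        assert reciprocal_overlap(0, 100, 25, 75) == pytest.approx(0.5)

    def test_symmetry(self):
        assert reciprocal_overlap(0, 100, 50, 160) == \
            reciprocal_overlap(50, 160, 0, 100)


class TestFrequencyAnnotate:
    def test_batch_fraction_counts_matching_carriers(self):
        cnv = make_call(chrom="1", start=1000, end=2000, first=0, last=0,
                        copy_number=1, sample="S0")
        same = make_call(chrom="1", start=1000, end=2000, first=0, last=0,
                         copy_number=1, sample="S1")
        gain = make_call(chrom="1", start=1000, end=2000, first=0, last=0,
                         copy_number=3, sample="S2")
        far = make_call(chrom="1", start=9000, end=9900, first=5, last=5,
                        copy_number=1, sample="S3")
        batch = {"S0": [cnv], "S1": [same], "S2": [gain], "S3": [far]}
        batch.update({f"S{i}": [] for i in range(4, 8)})
        freq, db = frequency_annotate(cnv, batch, AnnotationTables())
        # S0 itself and S1 carry it; the gain and the distant call do not
        assert freq == pytest.approx(2 / 8)
        assert db == 0.0

    def test_database_match_requires_type_and_half_overlap(self):
        db = pd.DataFrame([
            {"chrom": "1", "start": 1000, "end": 2000, "type": "loss",
             "frequency": 0.12},
            {"chrom": "1", "start": 1000, "end": 2000, "type": "gain",
             "frequency": 0.50},
        ])
        tables = AnnotationTables(inhouse_db=db)
        cnv = make_call(chrom="1", start=1100, end=2000, first=0, last=0,
                        copy_number=1)
        _, db_freq = frequency_annotate(cnv, {}, tables)
        assert db_freq == pytest.approx(0.12)  # the gain record is ignored
        # shift so reciprocal overlap drops below 0.5
        cnv2 = make_call(chrom="1", start=1800, end=2800, first=0, last=0,
                         copy_number=1)
        _, db_freq2 = frequency_annotate(cnv2, {}, tables)
        assert db_freq2 == 0.0

    def test_empty_batch_gives_zero(self):
        cnv = make_call()
        assert frequency_annotate(cnv, {}, AnnotationTables()) == (0.0, 0.0)


class TestSizeClass:
    def test_boundaries(self):
        def of(size):
            return size_class(make_call(start=0, end=size, first=0, last=0))

        assert of(EXON_LEVEL_MAX - 1) == "exon_level"
        assert of(EXON_LEVEL_MAX) == "gene_size"       # "<5 kb" is strict
        assert of(LARGE_MIN) == "gene_size"            # ">400 kb" is strict
        assert of(LARGE_MIN + 1) == "large"

    def test_published_examples(self):
        assert size_class(make_call(start=44489809, end=51220722,
                                    first=0, last=0)) == "large"
        assert size_class(make_call(start=79827886, end=79828230,
                                    first=0, last=0)) == "exon_level"
        assert size_class(make_call(start=43892159, end=43901532,
                                    first=0, last=0)) == "gene_size"


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

class TestAnnotateCalls:
    def test_full_annotation_of_study_call(self, study_grid, study_tables):
        case12 = make_call(chrom="15", start=43892159, end=43901532,
                           first=0, last=12, copy_number=1, sample="case12")
        [ann] = annotate_calls([case12], study_grid, study_tables)
        assert ann.size_class == "gene_size"
        assert any(g.gene == "STRC" for g in ann.genes)
        assert not ann.detectable["aCGH180K"]
        assert ann.detectable["MLPA"]
        assert ann.cytoband == ""  # no toy band table for chromosome 15
        assert ann.batch_freq == 0.0

    def test_merge_can_be_disabled(self, small_grid):
        calls = [make_call(first=0, last=1), make_call(first=4, last=5)]
        tables = AnnotationTables()
        assert len(annotate_calls(calls, small_grid, tables)) == 1
        assert len(annotate_calls(calls, small_grid, tables, merge=False)) == 2

    def test_terminal_flag(self, study_grid, study_tables):
        # case 1 runs to within a few targets of 22qter
        rows = study_grid.chrom_rows("22")
        starts = study_grid.df["start"].to_numpy()[rows]
        ends = study_grid.df["end"].to_numpy()[rows]
        import numpy as np

        hit = np.flatnonzero((starts < 51220722) & (ends > 44489809))
        cnv = make_call(chrom="22", start=44489809, end=51220722,
                        first=int(hit[0]), last=int(hit[-1]), copy_number=1)
        [ann] = annotate_calls([cnv], study_grid, study_tables)
        assert ann.terminal
        assert ann.qter_targets <= 10
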