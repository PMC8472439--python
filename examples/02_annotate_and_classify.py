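"""Annotate and classify the bundled diagnostic CNVs.

Runs each of the 20 bundled CNV segments through the annotation layer
(cytobands, gene/exon overlap, orthogonal-assay probe counts, size class)
and the rule cascade, using the bundled toy annotation tables.
"""

from exocnv import annotate_calls, classify
from exocnv.fixtures import (
    known_regions_frame,
    phenotype_genes_for,
    table1_calls,
    table1_frame,
    toy_annotation_tables,
    toy_grid,
)

grid = toy_grid()
tables = toy_annotation_tables()
regions = known_regions_frame()
categories = dict(zip(table1_frame()["case"], table1_frame()["categories"]))

print(f"{'case':>4} {'locus':<28} {'type':<4} {'size class':<10} "
      f"{'genes':<12} {'class':<17} rule")
for case, call in table1_calls(grid):
    [ann] = annotate_calls([call], grid, tables, merge=False)
    res = classify(ann, phenotype_genes=phenotype_genes_for(categories[case]),
                   known_regions=regions)
    locus = f"{call.chrom}:{call.start}-{call.end}"
    genes = ",".join(g.gene for g in ann.genes if g.n_exons) or "-"
    print(f"{case:>4} {locus:<28} {call.type:<4} {ann.size_class:<10} "
          f"{genes:<12} {res.classification:<17} {res.evidence[-1][0]}")
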