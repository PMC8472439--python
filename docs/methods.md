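# Methods

This note documents the statistical model, the fixed parameters and their
rationale, what the simulator does and does not emulate, and the known
limitations. Coordinates are 0-based half-open throughout; VCF output
converts to 1-based positions.

## Depth model

### Observed fraction

For a test sample with per-target read counts `o_t` and an aggregated
reference with counts `r_t`, the quantity modelled at each capture target is
the *observed fraction* `f_t = o_t / (o_t + r_t)`. Under copy number `c` the
expected fraction is

```
p_c = (c/2 · N_s) / (c/2 · N_s + N_r)
```

where `N_s` and `N_r` are the test and reference library totals over the
grid. Because the per-target capture efficiency multiplies test and
reference counts alike, it cancels from `f_t`; this is the core reason for
conditioning on the batch-mate reference instead of modelling absolute
depth. At `c = 0` the factor `c/2` is replaced by `ε = 0.01`, a floor
standing in for residual mismapped reads, so homozygous deletions keep a
proper likelihood.

### Beta-binomial likelihood

`o_t` given `n_t = o_t + r_t` is beta-binomial with mean `p_c` and
intra-class correlation `ρ`:

```
a = p (1 − ρ) / ρ,   b = (1 − p)(1 − ρ) / ρ
```

`ρ` absorbs the target-level overdispersion of capture sequencing that a
plain binomial would understate. It is estimated per sample by method of
moments from the per-target squared deviations,

```
ρ̂ = mean_t [ ((f_t − p)² − p(1−p)/n_t) / (p(1−p)(1 − 1/n_t)) ]
```

clipped to `[1e-6, 0.3]`. Targets with no reads at all contribute zero
log-likelihood (they carry no information under this model).

### Reference selection

Within a sequencing batch (32 samples for exomes, 8 for the small capture
design) the other samples are ranked by Pearson correlation of their raw
count profiles with the test sample, then added greedily in rank order
while the predicted beta-binomial variance of the aggregate observed
fraction keeps decreasing, capped at 10 references. Adding a sample
increases `n_t` (shrinking binomial noise) but can increase `ρ` (if the
sample's capture profile differs); the greedy criterion trades these off
without a free parameter.

### Segmentation

Copy states {0, 1, 2, 3, 4} are segmented per chromosome by a Viterbi pass.
The transition matrix has a strong stay-diploid prior: entering any
non-diploid state costs `t = 1e-4`; from a non-diploid state the remaining
probability mass is split evenly between extending the segment and
returning to diploid, so a CNV pays the entry penalty once rather than at
both ends. Ties are broken toward states closest to diploid, which makes
the called path unique and reproducible.

Each maximal non-diploid run becomes one call. Its copy number is the modal
state of the run (ties toward the less extreme state). Its quality is the
log10 likelihood ratio of the **full called path** (emissions plus the
entry, within-segment and exit transitions) against the all-diploid path
over the same targets. Including the transition terms in the score is what
keeps clean batches call-free: a 1–2-target noise excursion can win the
emission comparison but not the path comparison. Calls with quality below 3
(likelihood ratio 1000:1) are suppressed.

### Depth ratio and mosaicism

The segment depth ratio is computed against the *reference-scaled diploid
expectation*, `e_t = r_t · N_s / N_r`:

```
r̄ = Σ o_t / Σ e_t
```

(using the test sample's own totals in the denominator would bias gains
toward 1). For single-copy events, a CNV present in a cell fraction `f`
shifts the ratio to `1 + f (c − 2)/2`, giving

```
f = 2 (r̄ − 1)   for duplications,
f = 2 (1 − r̄)   for heterozygous deletions,
```

clamped to [0, 1]. A ratio of 1.29 on a gain therefore yields `f = 0.58`.
Fractions ≥ 0.95 are treated as constitutive and not reported as mosaic.

## Annotation and classification

* **Merging**: same-direction, same-copy-number calls on one chromosome
  separated by fewer than 3 intervening capture targets are merged (to a
  fixed point; order-independent). Merged quality is the maximum of the
  parts, the ratio their target-weighted mean.
* **Size classes**: `< 5 kb` exon-level, `> 400 kb` large, otherwise
  gene-sized. Both bounds are strict.
* **Orthogonal detectability**: a CNV counts as detectable by a microarray
  design if it contains ≥ 3 probes, and by an MLPA kit if it contains
  ≥ 2 probes.
* **Frequency**: a CNV matches a database record or batch-mate call when the
  direction agrees and the reciprocal overlap (minimum of the two mutual
  overlap fractions) is ≥ 0.5.
* **Classification cascade** (first match wins; every fired rule is recorded
  as evidence):
  * R0 — frequency > 0.01 in batch or databases → benign;
  * R1 — matches a known recurrent pathogenic region (direction + RO ≥ 0.5)
    → pathogenic;
  * R2 — hits a phenotype-matched gene with ClinGen haploinsufficiency
    (losses) or triplosensitivity (gains) score 3 → pathogenic;
  * R3 — hits a phenotype-matched disease gene without dosage-3 support
    → likely pathogenic;
  * R4 — rare and gene-impacting but unconnected to the phenotype → VUS;
  * R5 — no coding impact → likely benign.
  If no dosage table is available, R2/R3 are skipped with a warning.
* **Panel filtering**: in panel mode a CNV is kept only if it has coding
  overlap with a panel gene; genome-wide mode keeps everything. This is
  deliberately downstream of calling, so re-analysis with a wider panel
  needs no recomputation.

## Simulator

Counts are gamma-mixed Poisson (negative binomial), `var = μ + ρμ²`, with
lognormal sample effects (σ = 0.1) and target effects (σ = 0.5) around a
mean depth of 200 reads per target. Planted CNVs multiply the mean by
`1 + f (c − 2)/2`. An optional per-target scaling vector shared by the batch
emulates systematically poorly captured exons.

The generator is deliberately **not** the caller's beta-binomial: recovery
tests therefore exercise robustness to a mismatched noise process rather
than self-confirmation. It does not emulate GC waves, batch-correlated
capture drift, mappability artifacts, allele-specific signals, or reference
samples that themselves carry CNVs.

## Numerical and design choices

* Beta-binomial log-pmf via `scipy.stats.betabinom`; Viterbi in log space
  with an explicit tie-break order and a 1e-12 comparison epsilon; an
  exhaustive path enumerator serves as the test oracle.
* Problem sizes in tests and examples (1000-target grids, 32-sample
  batches) are this package's own choices for desk-scale runs.
* Deletions are intrinsically easier than duplications here: a loss moves
  the expected fraction by about 1.5× more than a gain does, so small
  (3–5-target) gains sit below the quality threshold at 200× while
  equally-sized losses are called reliably. The bundled diagnostic tables
  show the same asymmetry: every duplication among them is a large event.

## Limitations

* Single-sample inference against one aggregate; no joint calling across
  the batch and no explicit model of related samples.
* Copy numbers above 4 are truncated to 4; sex chromosomes are not treated
  specially (a reference of mixed sexes will bias X calls — compose batches
  or grids accordingly).
* A CNV shared by most of the batch (or present in the selected references)
  shrinks the apparent signal; the frequency rule is also, by design, blind
  to common pathogenic CNVs.
* Single-target events on poorly captured targets are frequently missed
  (≈ 0% sensitivity at 10% of nominal coverage in the acceptance suite);
  this failure mode is reproduced, not mitigated.
* The mosaic-fraction formula assumes single-copy events and an unbiased
  depth ratio; boundary truncation by the segmenter biases `f` downward
  slightly.
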