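#!/usr/bin/env bash
# End-to-end pipeline through the command line: simulate a batch, call one
# sample, annotate and classify the calls, and print the cohort report.
set -euo pipefail

out=$(mktemp -d)
trap 'rm -rf "$out"' EXIT

cat > "$out/spec.json" <<'EOF'
{"seed": 7, "n_targets": 1000,
 "spikes": [[0, 200, 209, 1, 1.0], [1, 600, 619, 3, 1.0]]}
EOF

exocnv simulate --spec "$out/spec.json" --out "$out/sim"
exocnv call --counts "$out/sim/counts.tsv" --targets "$out/sim/targets.bed" \
    --sample S000 --out "$out/calls.tsv"
exocnv annotate --calls "$out/calls.tsv" --targets "$out/sim/targets.bed" \
    --out "$out/annotated.tsv"
exocnv fixtures --out "$out/fixtures"
exocnv classify --annotated "$out/annotated.tsv" \
    --targets "$out/sim/targets.bed" \
    --dosage "$out/fixtures/gene_dosage.tsv" --mode genome_wide \
    --out "$out/classified.tsv"
cat "$out/classified.tsv"
exocnv report --cohort "$out/fixtures/cohort.tsv"
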