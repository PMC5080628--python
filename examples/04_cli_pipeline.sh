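#!/bin/sh
# Shell version of the cohort workflow: simulate -> compute -> supergenes ->
# Ks histogram.  All outputs are plain TSV with a run-manifest header line.
set -e
OUT=${1:-scratch/cli_demo}
mkdir -p "$OUT"

khscan simulate --codons 300 --genes 120 --branch-length 0.01 \
    --omega-high 1.0 --omega-low 0.1 --h-ranks 10 --seed 5 --out "$OUT/sim"

khscan compute --alignments "$OUT/sim" --kappa-policy global \
    --out "$OUT/results.tsv" --counts-out "$OUT/counts.tsv"

khscan supergenes --results "$OUT/results.tsv" --counts "$OUT/counts.tsv" \
    --bin 40 --out "$OUT/supergenes.tsv"

khscan ksdist --results "$OUT/results.tsv" --bin-width 0.01
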