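#!/bin/sh
# End-to-end run from the shell: simulate a cohort, then chain every
# stage (calibrate, preprocess, extract, modulation, factors, lifespan,
# report) into one output directory of TSV/CSV/JSON artifacts.
set -e
OUT=${1:-/tmp/pupilspan_demo}
pupilspan all --n 24 --trials-per-block 24 --seed 7 --out "$OUT"
echo
echo "artifacts written to $OUT:"
ls "$OUT"
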