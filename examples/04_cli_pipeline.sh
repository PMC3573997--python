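#!/usr/bin/env bash
# Full pipeline from the shell: simulate a cohort of motion CSVs, build the
# spectral feature matrix, and compare the groups.  All artifacts land in
# ./pipeline_demo/.
set -euo pipefail

OUT=pipeline_demo
mkdir -p "$OUT"

# two groups of six 10-minute records differing in dominant rhythm period
embryoflow simulate --kind cohort --seed 1 --n-per-group 6 \
    --duration 600 --out-dir "$OUT"

embryoflow spectra "$OUT"/*_motion.csv --fps 7.5 \
    --binset DANIO_XENOPUS_18 --out-dir "$OUT"

embryoflow compare "$OUT/features.csv" "$OUT/manifest.csv" \
    --seed 1 --out-dir "$OUT"

echo "artifacts:"
ls "$OUT"
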