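#!/bin/sh
# End-to-end shell workflow with the tsgpbm command.
# Generates synthetic fixtures, simulates the chain, computes distances,
# the noise floor, and a parameter sweep with an identifiability report.
set -e
workdir=$(mktemp -d)

cat > "$workdir/run.yaml" <<EOF
compartments:
  - name: C1
    kernel: {variant: square_step, R: 445.2188289917065, step: 50.0, beta0: 7.0e-12}
EOF

tsgpbm synthesize --scenario wetting-bimodal --out-dir "$workdir/fixtures"
tsgpbm simulate --config "$workdir/run.yaml" \
    --preblend "$workdir/fixtures/preblend.csv" --out-dir "$workdir/results"
echo "distance preblend -> C1:"
tsgpbm distance "$workdir/fixtures/preblend.csv" "$workdir/results/C1.csv"

tsgpbm synthesize --scenario repeats --seed 7 --replicates 10 \
    --noise-scale 0.05 --out-dir "$workdir/repeats"
echo "noise floor:"
tsgpbm noise-floor "$workdir"/repeats/repeat_*.csv

tsgpbm sweep --config "$workdir/run.yaml" \
    --target "$workdir/results/C1.csv" --inlet "$workdir/fixtures/preblend.csv" \
    --param R --from 150 --to 1200 --num 9 \
    --threshold-from "$workdir/repeats" --out "$workdir/sweep.json"
tsgpbm report "$workdir/sweep.json"
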