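#!/bin/sh
# End-to-end run of the command-line pipeline on synthetic data:
# simulate -> train -> analyze.  Outputs land under scratch/.
set -e

phroot simulate --out scratch/cli_data --n 5 --size 96 --seed 1
phroot train --dataset scratch/cli_data --out scratch/cli_model \
    --scale tiny --epochs 10 --seed 1
phroot analyze --input-table scratch/cli_data/samples.tsv \
    --model scratch/cli_model/model.npz --out scratch/cli_results \
    --seed 1 --mc-passes 10 --dropout-rate 0.5

echo "results:"
ls scratch/cli_results
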