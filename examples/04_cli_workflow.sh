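#!/usr/bin/env bash
# Stage-by-stage command-line workflow on files instead of in-memory data.
# Every intermediate is a plain-text table you can inspect.
set -euo pipefail

workdir=$(mktemp -d)
echo "working in $workdir"

# 1. simulate a small three-clone sample (writes FASTA, SAM, truth VCF)
clonehap simulate --length 30000 --subclones 3 --proportions 3:5:2 \
    --library 1000,50,250,100 --library 1500,75,250,50 \
    --epsilon 0.01 --seed 4 --out "$workdir/sim"

# 2. collapse read pairs to variant-position extracts + per-site VAFs
clonehap extract --sam "$workdir/sim/lib0.sam" --sam "$workdir/sim/lib1.sam" \
    --sites "$workdir/sim/truth.vcf" \
    --out "$workdir/vpe.tsv" --vaf-out "$workdir/vaf.tsv"

# 3. cluster VAFs into the clonal structure
clonehap cluster --vaf "$workdir/vaf.tsv" --seed 4 --out "$workdir/clonal"

# 4. assemble short chains (written for inspection; `phase` rebuilds them)
clonehap assemble --vpe "$workdir/vpe.tsv" --subclones 3 \
    --out "$workdir/chains.tsv"

# 5. phase into clonal haplotype fragments
clonehap phase --vpe "$workdir/vpe.tsv" --clusters "$workdir/clonal/clusters.tsv" \
    --out "$workdir/recon"

# 6. score against the simulation truth
clonehap evaluate --recon "$workdir/recon" --truth "$workdir/sim/truth.vcf" \
    --out "$workdir/metrics.json"

echo "metrics:"
cat "$workdir/metrics.json"
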