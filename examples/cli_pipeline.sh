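#!/usr/bin/env bash
# The same analysis as examples/quickstart.py, driven through the CLI.
# Writes everything under ./example_run/.
set -euo pipefail

out=example_run
mkdir -p "$out"

# 1. Simulate a fixture: GenBank contig + truth table + anchor table + spec echo.
dgrscan synth --seed 2024 --n-vr 2 --substitutions 12 --outdir "$out/fixture"

# 2. Scan around annotated RT genes for template/variable repeat pairs.
dgrscan scan "$out/fixture/contig.gbk" \
    --out "$out/hits.tsv" --alignments "$out/alignments.txt"

# 3. Classify the cassette architecture (group and subgroup).
dgrscan classify "$out/fixture/contig.gbk" --out "$out/cassettes.tsv"

# 4. RT protein motif report.
dgrscan motifs "$out/fixture/contig.gbk" --out "$out/motifs.tsv"

# 5. Substitution statistics over the reported hits.
dgrscan stats "$out/hits.tsv" --out "$out/stats.tsv"

column -t -s$'\t' "$out/hits.tsv" 2>/dev/null || cat "$out/hits.tsv"
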