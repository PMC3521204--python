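# dgrscan

Detection and analysis of diversity-generating retroelements (DGRs) in
bacterial and phage sequence data.

## The scientific problem

DGRs are genetic elements that mutate a chosen protein-coding region at an
enormous rate while leaving the rest of the genome untouched. A DGR consists
of a reverse transcriptase (RT) gene, a **template repeat** (TR) near it, and
one or more **variable repeats** (VRs) embedded in target genes. The RT copies
the TR through an error-prone RNA intermediate and writes the copy over the
VR. The errors are not random: they occur (almost) exclusively at positions
where the TR carries an adenine. A VR therefore looks like a near-exact copy
of the TR in which some subset of the TR's adenines has been replaced by C, G
or T. A TR with *n* adenines supports up to 4^n distinct VR sequences — for a
typical 30-adenine repeat that is ~10^18 protein variants from a single locus.

`dgrscan` finds such TR/VR pairs in annotated sequence records, classifies
the genomic architecture of each cassette, checks the RT protein for its
diagnostic motifs, and quantifies the substitution spectrum.

## The detection model

Around each annotated RT gene (± 5 kb by default) the scanner slides a 50 nt
window and asks, for every alignment offset, whether a second placement exists
at which **every non-adenine base matches exactly** — adenine is a *wildcard*
that may match anything. Matching seeds are extended to maximal length,
deduplicated, and kept when the template side has ≥ 10 adenines and the other
copy shows ≥ 7 substitutions at adenine positions. Exactly the same machinery
with the wildcard role given to T finds *inverted* elements whose TR/VR lie on
the strand opposite the RT gene. See `docs/methods.md` for the full model,
parameter semantics and design decisions.

The package has five parts (importable from `dgrscan`):

| module | contents |
| --- | --- |
| `dgrscan.io_genbank` | GenBank/FASTA reading and writing, RT anchors, regions, hit tables |
| `dgrscan.scan` | the wildcard sliding-window scanner and generalized (C/G/T) sweeps |
| `dgrscan.cassettes` | grouping hits into cassettes, target assignment, architecture groups 1–4 and subgroup letters |
| `dgrscan.motifs` | RT protein motifs: [Y/F]xDD, the upstream heptamer class, the basic-residue patch |
| `dgrscan.stats` | substitution profiles, exact repertoire diversity, χ² uniformity and proportionality tests |
| `dgrscan.synth` | the synthetic data generator used for validation (planted elements with known truth, plus decoys) |

## Worked example

`examples/quickstart.py` simulates a 12 kb contig with one RT gene, a TR and
two VRs, then runs the whole analysis in library calls. Its actual output:

```text
contig: synctg2024, 12000 bp
...
hit: TR (1401, 1511) / VR (399, 509), 30 adenines in TR, 12 substitutions {'T': 7, 'G': 4, 'C': 1}
hit: TR (1401, 1511) / VR (971, 1081), 30 adenines in TR, 12 substitutions {'C': 2, 'G': 9, 'T': 1}
architecture: group 1, subgroup 'f'
anchor  group subgroup  n_vr  tr_start  tr_end tr_strand     vr_intervals           targets flags
   rt1      1        f     2      1402    1511         + 400-509;972-1081 target_1;target_2
RT motifs: YMDD at 240, class canonical-SQ, charge patch 12/20 basic residues
mean mutation rate: 0.400
uniformity of substitution targets {'C': 3, 'G': 13, 'T': 8}: chi2=6.25, df=2, p=0.0439
repertoire upper bound for 30 adenines: 4**30 = 1152921504606846976
```

Both planted VRs are recovered with exact coordinates (the truth table plants
them at 399–509 and 971–1081, 0-based; the tabulated output is 1-based), every
substitution sits at a TR adenine, and none of the four planted decoy repeat
pairs (exact duplicate, 6-substitution repeat, non-adenine mismatches,
homopolymer) is reported.

The same pipeline through the command line (`examples/cli_pipeline.sh`):

```bash
dgrscan synth --seed 2024 --n-vr 2 --substitutions 12 --outdir fixture
dgrscan scan fixture/contig.gbk --out hits.tsv --alignments alignments.txt
dgrscan classify fixture/contig.gbk --out cassettes.tsv
dgrscan motifs fixture/contig.gbk --out motifs.tsv
dgrscan stats hits.tsv --out stats.tsv
```

which reports `2 hit(s)`, the cassette row
`rt1  1  f  2  1402  1511  +  400-509;972-1081  target_1;target_2`, and a
stats table with `chisq_uniform_p = 0.0439...`. All on-disk coordinates are
1-based inclusive; in-memory intervals are 0-based half-open.

`dgrscan scan --wildcard T` (or `dgrscan classify`, which sweeps
automatically) finds inverted, opposite-strand elements.

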