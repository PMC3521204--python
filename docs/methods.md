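# Methods

This document specifies the detection model, parameter semantics, statistics,
and the design of the synthetic validation generator. Conventions stated here
are the package's own design decisions; deviating callers should expect the
documented behavior, not an alternative interpretation.

## Coordinates

All in-memory intervals are 0-based half-open `(start, end)` on the forward
strand of the parent record. Every on-disk table and annotation (hit tables,
truth tables, cassette tables, GenBank features) is 1-based inclusive. The
reading and writing helpers perform the conversion; nothing else does.

## Detection model

A DGR copies its template repeat (TR) over each variable repeat (VR) through
an error-prone reverse transcript; errors occur at TR adenines. Consequently a
TR/VR pair is a pair of placements where **every non-adenine TR base matches
exactly** and some adenine positions differ. The scanner treats the adenine as
a *wildcard*:

* **Column rule.** A column (TR base *t*, VR base *v*) is clean when `t == v`
  or `t == wildcard`. `N` matches nothing, in either role.
* **Seeding.** Within the RT-anchored region, every alignment offset
  `d ∈ [window, L − window]` is tested in both template/copy role assignments.
  Column-match indicators are computed as vectorized byte comparisons; a seed
  is any window of `window_size` (default 50) consecutive clean columns whose
  template-side start respects `step`.
* **Extension.** Each seed is extended to maximal length by alternating one
  left step and one right step while the next column is clean. Extension never
  grows a match beyond the alignment offset (`length ≤ d`), so tandem
  (overlapping) repeats yield per-seed maximal matches rather than one
  self-overlapping match. For non-tandem offsets this decomposes each offset
  into maximal clean runs; the two formulations agree and the test suite
  cross-checks them against an independent seed-enumeration reference.
* **Deduplication.** Identical extended pairs are merged; a pair contained in
  a longer pair **at the same alignment offset** is dropped. A containing pair
  at a different offset is a distinct alignment and is kept.
* **Filters.** A pair is reported when the template side carries
  `min_wildcard_in_tr` wildcards (default 10) and the copy differs at
  `min_substitutions` wildcard positions (default 7). The defaults are the
  package's standard search settings; `min_substitutions=5` is the documented
  sensitivity setting and is expected to surface borderline repeats (the
  worked example's 6-substitution decoy is *correctly* reported at 5).
* **Role assignment.** In a reported hit the template role is the side whose
  wildcard positions explain all differences; the copy is the VR.

### Inverted elements

Some cassettes place the TR/VR on the strand opposite the RT gene. On the RT
strand their mutation channel appears at T (the complement of A). Scanning
the same region with `wildcard_base="T"` — and no other change — finds them;
`RepeatHit.on_element_strand()` re-expresses such a hit on its own strand,
where it is adenine-specific again. `sweep_wildcards` runs the C, G and T
channels; on genuine elements the C and G channels report nothing, which the
validation fixtures enforce structurally (below).

### Parameters (`ScanParams`)

| parameter | default | meaning |
| --- | --- | --- |
| `window_size` | 50 | seed length in clean columns |
| `step` | 1 | stride of template-side seed starts |
| `flank` | 5000 | nucleotides taken on each side of the RT CDS |
| `wildcard_base` | `A` | the mutable channel |
| `min_wildcard_in_tr` | 10 | minimum wildcards on the template side |
| `min_substitutions` | 7 | minimum visible substitutions in the copy |

`min_wildcard_in_tr ≥ min_substitutions` is enforced.

## Cassette architecture

Hits around one RT anchor are grouped into a cassette (they share one TR).
Classification happens in RT-coding-strand orientation; `'-'`-strand anchors
are normalized with the parent length.

* **Group 4** — TR strand differs from the RT strand (takes precedence).
* **Group 3** — TR overlaps the RT CDS (a TR fully inside the CDS is group 3
  with a flag).
* **Group 1** — TR entirely upstream of the RT CDS.
* **Group 2** — TR entirely downstream.

Each VR gets a placement code relative to the TR/RT pair: `U` (upstream of
both), `M` (between them), `D` (downstream of both), `O` (overlapping the RT
CDS), `X` (anything else). The subgroup letter enumerates arrangement
signatures by VR count first, then lexicographically over `(U, M, D, O, X)`:
one VR maps `U→a, M→b, D→c, O→d, X→e`; two VRs start at `UU→f`; three VRs
start at `UUU→"ae"` (spreadsheet-style letters beyond `z`). The mapping is
total and deterministic, so unseen arrangements still get a stable label.

`assign_targets` maps each VR to the smallest CDS that fully contains it on
the VR strand (the RT CDS is excluded); partial overlaps and intergenic VRs
leave the cassette flagged. `rescan_targets` slides the TR over the whole
record (both strands) to find distal perfect wildcard-matches beyond the
standard flank.

## RT protein motifs

* **Catalytic tetramer** `[Y/F]xDD`: first match scanning N→C; `x` is any of
  the 20 standard residues (`X` never matches).
* **Domain-4 heptamer** `[I/L/V]Gxxxxx`: only heptamers ending within the 100
  residues preceding the catalytic tetramer are considered and the nearest
  one wins; without a tetramer the first heptamer in the protein is taken.
  Its final dipeptide is classified `canonical-SQ`, a named variant
  (`SP, SH, NQ, PA, AQ, VQ`), or `other`; no heptamer is `absent`.
* **Basic patch**: the 20-residue window at or after the catalytic tetramer
  with the most R+K residues (ties to the smallest offset); `positive` fires
  at ≥ 10 (50 %).

## Statistics

* `diversity(n) = 4**n` as an exact Python integer — never floating point, so
  it is exact far beyond 53 bits (a 30-adenine repeat exceeds 2^53).
* `chisq_uniform(counts)`: Pearson χ² of the C/G/T substitution-target counts
  against uniform thirds, df = 2. For df = 2 the survival function has the
  closed form `p = exp(−χ²/2)`, which the implementation matches to ≤ 1e-10
  (property-tested) and which carries no numerical risk for any realistic
  count.
* `chisq_proportional(elements)`: for each target base, tests whether counts
  across elements are proportional to each element's adenine share. Expected
  cells below 1 are pooled smallest-first before the test (df = cells − 1
  after pooling); p-values use `scipy.stats.chi2.sf`.
* `profile(hits)`: per-element base frequencies at TR-adenine positions and a
  cross-element aggregate in which **elements are weighted equally**
  regardless of adenine count; standard deviations use `ddof = 1` (a single
  element reports SD 0).

## Synthetic validation generator (`dgrscan.synth`)

The generator emulates the real inputs the detector was designed for: an
annotated contig with an RT CDS, a planted TR, 1–4 VRs mutated only at TR
adenines, background sequence, and a fixed panel of decoy repeat pairs. Its
defaults are the package's standard study conditions: 12 kb background at
50 % GC, a 110 nt TR with 30 adenines, 15 substitutions per VR with target
bias C:G:T = 1:3:2, all four architecture groups, both RT strands, RT motif
profiles from canonical to absent. The truth table records every planted
coordinate, substitution offset and expected detectability, and round-trips
through disk with exact 1-based conversion.

### Structural guarantees, not tuned thresholds

The validation claims ("every planted VR recovered exactly", "decoys and
non-intended wildcard sweeps report nothing") are made true *by construction
of the fixtures*, never by adjusting scanner thresholds:

* **Boundary guards.** Each planted repeat copy is flanked by a fixed
  two-column guard (`TC…CT` around the TR, `AG…GA` around each VR). The first
  guard column is a C-against-G mismatch, the second T-against-A, so maximal
  extension beyond a planted boundary is at most one column in any wildcard
  channel — recovered coordinates are exact, not approximate.
* **Per-VR breakers.** All VR copies share the same guard bases, so a
  zero-offset VR-vs-VR comparison would pass straight through them. Each VR
  therefore also carries a distinct 4 nt breaker outside its guards; the
  breakers pairwise disagree in a C/G column and in an A/T column, killing
  any VR-vs-VR clean run within four columns of the boundary in every
  channel. This caps the generator at 4 VRs per cassette.
* **Channel-inertness rejection sampling.** Every candidate VR is re-drawn
  until, for each non-intended wildcard channel and each ordered pairing with
  the TR and the other VRs — evaluated on the copies *with their real planted
  boundary context* — no single maximal clean run is both ≥ `window_size`
  long and ≥ 7 visible substitutions. A reported hit is exactly one maximal
  clean run, so this predicate mirrors the detector; the per-run accounting
  matters (a long clean run and seven visible substitutions in *different*
  runs is harmless and must not cause rejection, or TRs with an adenine-sparse
  stretch could never be planted).
* **Decoys.** Four planted near-miss repeat pairs per fixture: an exact
  duplicate (0 substitutions), a 6-substitution repeat just below the default
  threshold (all targets T, so no C/G channel can accumulate 7 visible
  substitutions), a pair with 5 alternating non-adenine C↔G mismatches
  (breaks every channel's runs), and a 24 nt homopolymer.

### Known limitations of the emulation

* A wildcard homopolymer tract of window length (e.g. 50 consecutive A's)
  matches *anything* under the column rule, so the detector floods on it.
  This is inherent to the algorithm, not the generator; the decoy homopolymer
  is kept at 24 nt (below half a window) for that reason, and real-data users
  should mask long homopolymers first.
* Background sequence is i.i.d. at a fixed GC; real genomic context has
  repeats and compositional structure the fixtures do not model. The
  structural guarantees above are therefore about planted elements and
  decoys, not about arbitrary natural sequence.
* The generator writes single-contig records with one RT per fixture; multi-RT
  and multi-record inputs are supported by the scanner and CLI but exercised
  with composed fixtures rather than a dedicated generator mode.

## Numerical choices

* Column comparisons are `numpy` `uint8` vector operations over the encoded
  region; seeds come from cumulative-sum window counts. Memory is O(L) per
  alignment offset.
* Exact integer arithmetic wherever exactness is claimed (`diversity`,
  coordinates); floating point only in statistics, with closed forms used
  where they are both faster and exactly testable (df = 2 χ²).
* All randomness flows through `numpy.random.Generator` seeded explicitly;
  fixtures are reproducible byte-for-byte from their spec, and the spec is
  echoed to `spec.yaml` alongside every written fixture.
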