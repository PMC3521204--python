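"""End-to-end library walkthrough: simulate, scan, classify, summarize.

Run from the repository root:

    python examples/quickstart.py
"""

from dgrscan.cassettes import (
    assign_targets,
    cassette_table,
    classify_structure,
    group_cassettes,
)
from dgrscan.io_genbank import extract_region
from dgrscan.motifs import analyze_protein
from dgrscan.scan import ScanParams, scan_region
from dgrscan.stats import chisq_uniform, diversity, profile
from dgrscan.synth import PlantSpec, fixture_anchor, make_genome

# 1. Simulate a contig carrying one element: a reverse-transcriptase (RT)
#    gene, a template repeat (TR) and two variable repeats (VRs) that differ
#    from the TR only at TR-adenine positions.
spec = PlantSpec(seed=2024, n_vr=2, substitutions_per_vr=12)
contig, truth = make_genome(spec)
print(f"contig: {contig.id}, {len(contig)} bp")
print(truth[["name", "kind", "start", "end", "strand"]].to_string(index=False))

# 2. Scan the neighborhood of the RT anchor for TR/VR pairs.
anchor = fixture_anchor(contig)
region = extract_region(contig, anchor, flank=5000)
hits = scan_region(region, ScanParams())
for h in hits:
    print(
        f"hit: TR {h.tr_interval} / VR {h.vr_interval}, "
        f"{h.n_wildcard_tr} adenines in TR, "
        f"{len(h.substitutions)} substitutions {h.counts_by_target}"
    )

# 3. Group the hits into a cassette, assign each VR to the coding sequence
#    that contains it, and classify the architecture.
(cassette,) = group_cassettes(hits, anchor)
cassette = assign_targets(cassette, contig.features)
group, subgroup = classify_structure(cassette, parent_length=len(contig))
print(f"architecture: group {group}, subgroup {subgroup!r}")
print(cassette_table([cassette]).to_string(index=False))

# 4. Inspect the RT protein for the catalytic and accessory motifs.
rt_cds = next(f for f in contig.features if f.kind == "CDS"
              and f.qualifiers.get("locus_tag") == "rt1")
report = analyze_protein("rt1", rt_cds.qualifiers["translation"])
print(f"RT motifs: {report.ydd.tetramer} at {report.ydd.offset}, "
      f"class {report.motif4.klass}, "
      f"charge patch {report.charge_patch.count}/20 basic residues")

# 5. Substitution statistics across the element.
prof = profile(hits)
print(f"mean mutation rate: {prof.mean_mutation_rate:.3f}")
pooled = {b: int(prof.per_element[f"count_{b}"].sum()) for b in "CGT"}
stat, df, p = chisq_uniform(pooled)
print(f"uniformity of substitution targets {pooled}: "
      f"chi2={stat:.2f}, df={df}, p={p:.3g}")
n_a = hits[0].n_wildcard_tr
print(f"repertoire upper bound for {n_a} adenines: 4**{n_a} = {diversity(n_a)}")
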