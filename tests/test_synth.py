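import pandas as pd
import pytest

from dgrscan.errors import InputError, SizingError
from dgrscan.io_genbank import extract_region, read_sequences
from dgrscan.scan import ScanParams, revcomp, scan_region
from dgrscan.synth import (
    PlantSpec,
    fixture_anchor,
    make_genome,
    make_repeat_sequence,
    read_truth_table,
    spec_to_dict,
    write_fixture,
    write_truth_table,
)


def test_reproducible_and_seed_sensitive():
    a1, t1 = make_genome(PlantSpec(seed=9))
    a2, t2 = make_genome(PlantSpec(seed=9))
    b, tb = make_genome(PlantSpec(seed=10))
    assert a1.residues == a2.residues
    assert t1.equals(t2)
    assert [(f.kind, f.start, f.end, f.strand) for f in a1.features] == [
        (f.kind, f.start, f.end, f.strand) for f in a2.features
    ]
    assert a1.residues != b.residues


def _element_view(seq, row):
    piece = seq.residues[row.start : row.end]
    return revcomp(piece) if row.strand == "-" else piece


@pytest.mark.parametrize("group,rt_strand", [(1, "+"), (2, "-"), (3, "+"), (4, "+"), (4, "-")])
def test_vr_differs_only_at_tr_adenines(group, rt_strand):
    spec = PlantSpec(seed=31 + group, arrangement_group=group, rt_strand=rt_strand)
    seq, truth = make_genome(spec)
    tr = _element_view(seq, truth[truth.kind == "TR"].iloc[0])
    assert tr.count("A") == spec.n_adenines_tr
    for _, row in truth[truth.kind == "VR"].iterrows():
        vr = _element_view(seq, row)
        offsets = [int(x) for x in row.substitution_offsets.split(",")]
        diffs = [i for i, (a, b) in enumerate(zip(tr, vr)) if a != b]
        assert diffs == offsets
        assert all(tr[i] == "A" and vr[i] in "CGT" for i in diffs)
        assert len(diffs) == int(row.n_substitutions)


def test_group3_tr_overlaps_rt_tail():
    spec = PlantSpec(seed=77, arrangement_group=3)
    seq, truth = make_genome(spec)
    rt = truth[truth.kind == "RT"].iloc[0]
    tr = truth[truth.kind == "TR"].iloc[0]
    assert tr.start == rt.end - spec.group3_overlap
    assert tr.end > rt.end


def test_group4_strands_opposite():
    seq, truth = make_genome(PlantSpec(seed=78, arrangement_group=4))
    rt = truth[truth.kind == "RT"].iloc[0]
    assert all(
        row.strand != rt.strand
        for _, row in truth[truth.kind.isin(["TR", "VR"])].iterrows()
    )


def test_intervals_disjoint_except_group3_overlap():
    for seed, group in ((1, 1), (2, 2), (3, 4)):
        _, truth = make_genome(PlantSpec(seed=seed, arrangement_group=group, n_vr=2 if group < 3 else 1))
        rows = truth[~truth.kind.isin(["target_CDS"])]
        ivs = sorted((r.start, r.end, r["name"]) for _, r in rows.iterrows())
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
            assert e1 <= s2, f"{n1} overlaps {n2}"


def test_vr_inside_its_target_cds():
    _, truth = make_genome(PlantSpec(seed=41, n_vr=2))
    for i in (1, 2):
        vr = truth[truth["name"] == f"VR{i}"].iloc[0]
        tgt = truth[truth["name"] == f"target_{i}"].iloc[0]
        assert tgt.start < vr.start and vr.end < tgt.end
        assert tgt.strand == vr.strand


def test_intergenic_vr_has_no_target():
    _, truth = make_genome(PlantSpec(seed=42, n_vr=2, vr_intergenic=(1,)))
    assert "target_1" in set(truth["name"])
    assert "target_2" not in set(truth["name"])


def test_detectability_contract():
    for seed, group in ((51, 1), (52, 2), (53, 3), (54, 4)):
        spec = PlantSpec(seed=seed, arrangement_group=group)
        seq, truth = make_genome(spec)
        region = extract_region(seq, fixture_anchor(seq))
        hits = scan_region(region, ScanParams())
        n_expected = int(truth[truth.kind == "VR"].detectable_default.astype(int).sum())
        assert len(hits) == n_expected


def test_decoys_only_contract():
    spec = PlantSpec.decoys_only(seed=61)
    seq, truth = make_genome(spec)
    assert set(truth.kind) == {
        "RT", "decoy_exact_duplicate", "decoy_low_substitution",
        "decoy_non_wildcard_mismatch", "decoy_homopolymer",
    }
    region = extract_region(seq, fixture_anchor(seq))
    assert scan_region(region, ScanParams()) == []


def test_low_substitution_decoy_is_a_repeat_below_threshold():
    seq, truth = make_genome(PlantSpec.decoys_only(seed=62))
    a = truth[truth["name"] == "decoy2_a"].iloc[0]
    b = truth[truth["name"] == "decoy2_b"].iloc[0]
    t = seq.residues[a.start : a.end]
    v = seq.residues[b.start : b.end]
    diffs = [i for i, (x, y) in enumerate(zip(t, v)) if x != y]
    assert len(diffs) == 6 and all(t[i] == "A" for i in diffs)


def test_fixture_roundtrip(tmp_path):
    spec = PlantSpec(seed=71, arrangement_group=2)
    paths = write_fixture(spec, tmp_path / "fx")
    (rec,) = read_sequences(paths["genbank"])
    seq, truth = make_genome(spec)
    assert rec.residues == seq.residues
    back = read_truth_table(paths["truth"])
    assert list(back["start"]) == list(truth["start"])
    assert list(back["end"]) == list(truth["end"])
    assert list(back["substitution_offsets"]) == [
        str(s) for s in truth["substitution_offsets"]
    ]
    import yaml

    echoed = yaml.safe_load(open(paths["spec"]))
    assert echoed == spec_to_dict(spec)
    anchors = open(paths["anchors"]).read().splitlines()
    assert anchors[0].split("\t")[0] == "sequence_id" and len(anchors) == 2


def test_truth_table_disk_is_one_based(tmp_path):
    _, truth = make_genome(PlantSpec(seed=72))
    p = tmp_path / "truth.tsv"
    write_truth_table(truth, p)
    disk = pd.read_csv(p, sep="\t", keep_default_na=False)
    assert list(disk["start"]) == [s + 1 for s in truth["start"]]
    vr_mem = truth[truth.kind == "VR"].iloc[0]
    vr_disk = disk[disk.kind == "VR"].iloc[0]
    mem_off = [int(x) for x in vr_mem.substitution_offsets.split(",")]
    disk_off = [int(x) for x in vr_disk.substitution_offsets.split(",")]
    assert disk_off == [o + 1 for o in mem_off]


def test_make_repeat_sequence_truth():
    s, truth = make_repeat_sequence(5, length=1200, tr_length=40, n_adenines=10, n_substitutions=6)
    ts, te = truth["tr_interval"]
    vs, ve = truth["vr_interval"]
    tr, vr = s[ts:te], s[vs:ve]
    diffs = [i for i, (a, b) in enumerate(zip(tr, vr)) if a != b]
    assert diffs == truth["substitution_offsets"]
    assert tr.count("A") == 10


def test_spec_validation():
    with pytest.raises(InputError):
        PlantSpec(seed=1, n_adenines_tr=200, tr_length=100)
    with pytest.raises(InputError):
        PlantSpec(seed=1, substitutions_per_vr=40, n_adenines_tr=30)
    with pytest.raises(InputError):
        PlantSpec(seed=1, arrangement_group=5)
    with pytest.raises(InputError):
        PlantSpec(seed=1, rt_strand="x")
    with pytest.raises(InputError):
        PlantSpec(seed=1, decoys=("sneaky",))
    with pytest.raises(InputError):
        PlantSpec(seed=1, low_substitution_count=9)
    with pytest.raises(InputError):
        PlantSpec(seed=1, n_vr=2, vr_placements=("U",))
    # placement codes incompatible with the group are caught at build time
    with pytest.raises(InputError):
        make_genome(PlantSpec(seed=1, arrangement_group=4, vr_placements=("M",)))


def test_sizing_error_on_small_background():
    with pytest.raises(SizingError):
        make_genome(PlantSpec(seed=1, background_length=2000))
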