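import itertools

import pytest

from dgrscan.cassettes import (
    DGRCassette,
    _subgroup_letter,
    assign_targets,
    cassette_table,
    classify_structure,
    group_cassettes,
    rescan_targets,
)
from dgrscan.errors import InputError
from dgrscan.io_genbank import AnnotatedSequence, Feature, RTAnchor
from dgrscan.scan import RepeatHit, revcomp
from dgrscan.synth import PlantSpec, fixture_anchor, make_genome


def _hit(tr, vr, strand="+"):
    return RepeatHit(
        parent_id="p", tr_interval=tr, vr_interval=vr, length=tr[1] - tr[0],
        strand_relation="same" if strand == "+" else "inverted",
        wildcard_base="A", n_wildcard_tr=20,
        substitutions=[(0, "A", "G")] * 1, counts_by_target={"G": 1},
        element_strand=strand,
    )


ANCHOR = RTAnchor("p", (5000, 6200), "+", "rt")


def test_group_cassettes_merges_shared_tr():
    hits = [
        _hit((4000, 4110), (1000, 1110)),
        _hit((4000, 4110), (2000, 2110)),
        _hit((8000, 8110), (9000, 9110)),
    ]
    cassettes = group_cassettes(hits, ANCHOR)
    assert len(cassettes) == 2
    a, b = cassettes
    assert a.tr_interval == (4000, 4110) and a.vrs == [(1000, 1110), (2000, 2110)]
    assert b.tr_interval == (8000, 8110) and b.n_vr == 1


def test_group_cassettes_order_invariant():
    hits = [
        _hit((4000, 4110), (1000, 1110)),
        _hit((4002, 4112), (2000, 2110)),  # >=90% reciprocal overlap
        _hit((8000, 8110), (9000, 9110)),
    ]
    base = None
    for perm in itertools.permutations(hits):
        cs = group_cassettes(list(perm), ANCHOR)
        shape = [(c.tr_interval, tuple(c.vrs)) for c in cs]
        base = base or shape
        assert shape == base
    assert base[0][0] == (4000, 4112)  # union TR


@pytest.mark.parametrize(
    "tr,strand,expected",
    [
        ((3000, 3110), "+", 1),   # upstream
        ((8000, 8110), "+", 2),   # downstream
        ((6150, 6260), "+", 3),   # overlaps RT 3' end
        ((3000, 3110), "-", 4),   # opposite strand wins
        ((6150, 6260), "-", 4),   # strand precedence over overlap
    ],
)
def test_classify_groups(tr, strand, expected):
    c = DGRCassette(
        anchor=ANCHOR, tr_interval=tr, tr_strand=strand,
        vrs=[(1000, 1110)], vr_strand=strand,
    )
    group, _ = classify_structure(c)
    assert group == expected


def test_classify_tr_inside_rt_flag():
    c = DGRCassette(
        anchor=ANCHOR, tr_interval=(5100, 5210), tr_strand="+",
        vrs=[(1000, 1110)], vr_strand="+",
    )
    group, _ = classify_structure(c)
    assert group == 3 and "TR inside RT CDS" in c.flags


def test_classify_minus_anchor_normalization():
    # mirror of the upstream case on a 20 kb parent: on '-' the TR with larger
    # coordinates is 5' of the RT in coding orientation
    L = 20000
    anchor = RTAnchor("p", (L - 6200, L - 5000), "-", "rt")
    c = DGRCassette(
        anchor=anchor, tr_interval=(L - 3110, L - 3000), tr_strand="-",
        vrs=[(L - 1110, L - 1000)], vr_strand="-",
    )
    group, sub = classify_structure(c, parent_length=L)
    assert (group, sub) == (1, "a")
    with pytest.raises(InputError):
        classify_structure(c)  # parent_length required on '-'


def test_subgroup_letters():
    # one VR: U,M,D,O,X -> a..e; two VRs start at f
    assert [_subgroup_letter(1, [c]) for c in "UMDOX"] == list("abcde")
    assert _subgroup_letter(2, ["U", "U"]) == "f"
    assert _subgroup_letter(2, ["U", "M"]) == "g"
    # three VRs start at index 5 + 25 = 30 -> spreadsheet letters "ae"
    assert _subgroup_letter(3, ["U", "U", "U"]) == "ae"
    # prototypical VR-TR-RT cassette is group 1, subgroup a
    c = DGRCassette(
        anchor=ANCHOR, tr_interval=(3000, 3110), tr_strand="+",
        vrs=[(1000, 1110)], vr_strand="+",
    )
    assert classify_structure(c) == (1, "a")


def test_vr_placement_codes():
    c = DGRCassette(
        anchor=ANCHOR, tr_interval=(3000, 3110), tr_strand="+",
        vrs=[(1000, 1110), (4000, 4110), (5500, 5610), (9000, 9110)],
        vr_strand="+",
    )
    classify_structure(c)
    # codes U (before both), M (between TR and RT), O (overlaps RT), D (after)
    assert c.subgroup == _subgroup_letter(4, ["U", "M", "O", "D"])


def test_assign_targets_smallest_containing_cds():
    features = [
        Feature("CDS", 5000, 6200, "+", {"locus_tag": "rt"}),        # the RT
        Feature("CDS", 900, 1500, "+", {"locus_tag": "big"}),
        Feature("CDS", 950, 1200, "+", {"locus_tag": "small"}),
        Feature("CDS", 1990, 2050, "+", {"locus_tag": "partial"}),
    ]
    c = DGRCassette(
        anchor=ANCHOR, tr_interval=(3000, 3110), tr_strand="+",
        vrs=[(1000, 1110), (2000, 2110)], vr_strand="+",
    )
    assign_targets(c, features)
    assert c.target_orfs[0].qualifiers["locus_tag"] == "small"
    assert c.target_orfs[1] is None  # only partial overlap
    assert "unassigned VR" in c.flags


def test_assign_targets_respects_strand_and_rt_exclusion():
    features = [
        Feature("CDS", 5000, 6200, "+", {"locus_tag": "rt"}),
        Feature("CDS", 900, 1500, "-", {"locus_tag": "wrong_strand"}),
    ]
    c = DGRCassette(
        anchor=ANCHOR, tr_interval=(5100, 5210), tr_strand="+",
        vrs=[(1000, 1110), (5300, 5410)], vr_strand="+",
    )
    assign_targets(c, features)
    assert c.target_orfs == [None, None]  # RT CDS is never a target


def test_rescan_targets_finds_distal_copy():
    seq, truth = make_genome(PlantSpec(seed=21))
    tr_row = truth[truth.kind == "TR"].iloc[0]
    tr_seq = seq.residues[tr_row.start : tr_row.end]
    vr_row = truth[truth.kind == "VR"].iloc[0]
    # plant an extra VR copy far beyond any flank, on the minus strand
    extra = revcomp(seq.residues[vr_row.start : vr_row.end])
    residues = seq.residues[:11000] + extra + seq.residues[11000 + len(extra):]
    seq2 = AnnotatedSequence(id=seq.id, residues=residues, features=seq.features)
    found = rescan_targets(seq2, tr_seq, (tr_row.start, tr_row.end))
    ivs = {(f["interval"], f["strand"]) for f in found}
    assert ((vr_row.start, vr_row.end), "+") in ivs
    assert ((11000, 11000 + len(extra)), "-") in ivs


def test_cassette_table(tmp_path):
    c = DGRCassette(
        anchor=ANCHOR, tr_interval=(3000, 3110), tr_strand="+",
        vrs=[(1000, 1110)], vr_strand="+",
    )
    classify_structure(c)
    df = cassette_table([c], tmp_path / "c.tsv")
    row = df.iloc[0]
    assert (row.group, row.subgroup, row.n_vr) == (1, "a", 1)
    assert (row.tr_start, row.tr_end) == (3001, 3110)  # 1-based inclusive
    assert row.vr_intervals == "1001-1110"
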