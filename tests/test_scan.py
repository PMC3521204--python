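import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgrscan.errors import InputError
from dgrscan.scan import (
    RepeatHit,
    ScanParams,
    align_pair,
    extend_match,
    parse_alignment,
    revcomp,
    scan_residues,
)
from dgrscan.synth import make_repeat_sequence

from _oracle import hits_as_tuples, oracle_scan

dna = st.text(alphabet="ACGT", min_size=25, max_size=140)
dna_n = st.text(alphabet="ACGTN", min_size=25, max_size=120)


def test_revcomp():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(window_size=5),
        dict(step=0),
        dict(min_substitutions=0),
        dict(min_wildcard_in_tr=3, min_substitutions=5),
        dict(wildcard_base="N"),
        dict(flank=-1),
    ],
)
def test_params_validation(kwargs):
    with pytest.raises(InputError):
        ScanParams(**kwargs)


@given(dna)
def test_matches_oracle_small_window(s):
    p = ScanParams(window_size=10, min_wildcard_in_tr=1, min_substitutions=1)
    got = hits_as_tuples(scan_residues(s, p))
    assert got == oracle_scan(s, window=10, min_wildcard=1, min_substitutions=1)


@given(dna_n, st.sampled_from("ACGT"), st.sampled_from([1, 2, 3]))
def test_matches_oracle_wildcards_steps_and_n(s, wc, step):
    p = ScanParams(
        window_size=10, min_wildcard_in_tr=2, min_substitutions=1,
        wildcard_base=wc, step=step,
    )
    got = hits_as_tuples(scan_residues(s, p))
    assert got == oracle_scan(
        s, window=10, min_wildcard=2, min_substitutions=1, wildcard=wc, step=step
    )


@settings(max_examples=15)
@given(st.integers(0, 10_000))
def test_matches_oracle_planted_2kb(seed):
    s, _ = make_repeat_sequence(seed, length=2000, n_substitutions=8)
    for ms in (7, 5):
        got = hits_as_tuples(scan_residues(s, ScanParams(min_substitutions=ms)))
        assert got == oracle_scan(s, min_substitutions=ms)


def test_planted_pair_recovered_exactly():
    s, truth = make_repeat_sequence(123, length=2000, n_substitutions=8)
    (hit,) = scan_residues(s, ScanParams())
    assert hit.tr_interval == truth["tr_interval"]
    assert hit.vr_interval == truth["vr_interval"]
    assert [o for o, _, _ in hit.substitutions] == truth["substitution_offsets"]
    assert all(t == "A" for _, t, _ in hit.substitutions)


def test_deterministic():
    s, _ = make_repeat_sequence(7, length=1500)
    a = hits_as_tuples(scan_residues(s, ScanParams()))
    b = hits_as_tuples(scan_residues(s, ScanParams()))
    assert a == b and a


def test_random_background_yields_nothing():
    for seed in range(5):
        s, _ = make_repeat_sequence(seed, length=2500, plant=False)
        assert scan_residues(s, ScanParams()) == []


def test_substitution_threshold_semantics():
    s, truth = make_repeat_sequence(55, length=2000, n_substitutions=6)
    assert scan_residues(s, ScanParams()) == []  # 6 < 7
    hits = scan_residues(s, ScanParams(min_substitutions=5))
    assert [h.vr_interval for h in hits] == [truth["vr_interval"]]


def test_wildcard_count_threshold_semantics():
    s, truth = make_repeat_sequence(
        77, length=2000, tr_length=60, n_adenines=9, n_substitutions=8
    )
    assert scan_residues(s, ScanParams()) == []  # 9 adenines < 10
    hits = scan_residues(s, ScanParams(min_wildcard_in_tr=9, min_substitutions=7))
    assert [h.vr_interval for h in hits] == [truth["vr_interval"]]


def test_non_wildcard_mismatch_breaks_match():
    s, truth = make_repeat_sequence(99, length=2000, tr_length=50, n_adenines=12)
    ts, te = truth["tr_interval"]
    # corrupt one central non-A template base in the VR copy
    off = next(
        i for i in range(20, 30) if s[ts + i] != "A"
    )
    vs = truth["vr_interval"][0]
    bad = {"C": "G", "G": "C", "T": "G"}[s[ts + off]]
    s2 = s[: vs + off] + bad + s[vs + off + 1 :]
    assert scan_residues(s2, ScanParams()) == []


def test_window_shorter_than_region():
    assert scan_residues("ACGT", ScanParams()) == []


def test_extend_match_alternates_under_overlap_cap():
    # periodic sequence, period 12: every column at offset 12 matches, so the
    # overlap cap (length <= offset) binds.  From seed (2, 14, 10) there are
    # two spare columns: alternation takes one left then one right.
    s = ("ACGTACGTACGT" * 4)[:48]
    assert extend_match(s, 2, 14, 10, "A") == (1, 13, 12)


def test_extend_match_stops_at_bounds_and_mismatch():
    #            0123456789012345
    s = "TTGCGCGTTTGCGCAT"
    # seeds: s[1:8] vs s[8:15] differ at last column (T vs A with wildcard A ok? T!=A)
    ts, vs, ln = extend_match(s, 1, 9, 5, "A")
    assert (ts, vs) == (0, 8) or ln >= 5  # grew to a maximal pair
    # no further single-step extension possible on either side
    from dgrscan.scan import _column_ok

    gap = vs - ts
    if ts > 0 and ln < gap:
        assert not _column_ok(s[ts - 1], s[vs - 1], "A")
    if vs + ln < len(s) and ln < gap:
        assert not _column_ok(s[ts + ln], s[vs + ln], "A")


def test_inverted_scan_via_reverse_complement():
    s, truth = make_repeat_sequence(42, length=2000, n_substitutions=8)
    L = len(s)
    rc = revcomp(s)
    hits = scan_residues(rc, ScanParams(wildcard_base="T"))
    assert len(hits) == 1
    h = hits[0]
    assert h.strand_relation == "inverted"
    # intervals mirror the planted ones
    mirror = lambda iv: (L - iv[1], L - iv[0])
    assert {h.tr_interval, h.vr_interval} == {
        mirror(truth["tr_interval"]),
        mirror(truth["vr_interval"]),
    }
    # element-strand view restores adenine-specific substitutions
    e = h.on_element_strand()
    assert e.wildcard_base == "A"
    assert all(t == "A" for _, t, _ in e.substitutions)
    assert [o for o, _, _ in e.substitutions] == truth["substitution_offsets"]


def test_align_pair_roundtrip():
    s, _ = make_repeat_sequence(11, length=1500, n_substitutions=9)
    (hit,) = scan_residues(s, ScanParams())
    text = align_pair(hit, width=40)
    tr, vr, subs = parse_alignment(text)
    assert tr == hit.tr_seq and vr == hit.vr_seq
    assert [(o, t, v) for o, t, v in subs] == hit.substitutions
    assert f"substitutions={len(hit.substitutions)}" in text


def test_align_pair_requires_sequences():
    h = RepeatHit(
        parent_id="x", tr_interval=(0, 5), vr_interval=(10, 15), length=5,
        strand_relation="same", wildcard_base="A", n_wildcard_tr=2,
        substitutions=[], counts_by_target={},
    )
    with pytest.raises(InputError):
        align_pair(h)
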