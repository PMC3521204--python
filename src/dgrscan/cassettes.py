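"""Assemble repeat hits into DGR cassettes and classify their architecture.

A cassette is one RT gene plus one TR and one or more VRs.  Architecture
groups follow the relative placement of TR and RT, evaluated in RT-coding
strand orientation:

* group 1 — TR upstream (5') of the RT CDS;
* group 2 — TR downstream (3') of the RT CDS;
* group 3 — TR overlaps the RT CDS;
* group 4 — TR on the opposite strand from the RT (takes precedence).

Subgroups encode the number and placement of VRs.  Each VR, ordered by
position, receives a placement code: ``U`` entirely 5' of both TR and RT,
``M`` between them, ``D`` entirely 3' of both, ``O`` overlapping the RT CDS,
``X`` anything else.  Signatures are ranked by (n_vr, lexicographic code
order U<M<D<O<X) and mapped to letters a, b, c, ..., which pins the
prototypical VR-TR-RT arrangement to group 1 subgroup "a".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DgrScanError, InputError
from .io_genbank import AnnotatedSequence, Feature, RTAnchor
from .scan import RepeatHit

_CODES = "UMDOX"


@dataclass
class DGRCassette:
    """An RT anchor with its merged TR, the VR set, and classification."""

    anchor: RTAnchor
    tr_interval: tuple[int, int]
    tr_strand: str
    vrs: list[tuple[int, int]]
    vr_strand: str
    hits: list[RepeatHit] = field(default_factory=list)
    target_orfs: list[Optional[Feature]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    group: Optional[int] = None
    subgroup: Optional[str] = None

    @property
    def n_vr(self) -> int:
        return len(self.vrs)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def group_cassettes(
    hits: Sequence[RepeatHit], anchor: RTAnchor, merge_overlap: float = 0.9
) -> list[DGRCassette]:
    """Merge hits whose TRs reciprocally overlap >= ``merge_overlap``.

    Each merged set becomes one cassette whose TR is the union interval and
    whose VRs are the distinct VR intervals sorted by position.  Hit order
    never changes the result.
    """
    hits = sorted(hits, key=lambda h: (h.tr_interval, h.vr_interval))
    if not hits:
        return []
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _reciprocal_overlap(hits[i].tr_interval, hits[j].tr_interval) >= merge_overlap:
                parent[find(i)] = find(j)
    groups: dict[int, list[RepeatHit]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])

    cassettes = []
    for members in groups.values():
        tr = (
            min(h.tr_interval[0] for h in members),
            max(h.tr_interval[1] for h in members),
        )
        vrs = sorted({tuple(h.vr_interval) for h in members})
        cassettes.append(
            DGRCassette(
                anchor=anchor,
                tr_interval=tr,
                tr_strand=members[0].element_strand,
                vrs=[tuple(v) for v in vrs],
                vr_strand=members[0].element_strand,
                hits=members,
            )
        )
    cassettes.sort(key=lambda c: c.tr_interval)
    return cassettes


def assign_targets(
    cassette: DGRCassette, features: Sequence[Feature]
) -> DGRCassette:
    """Assign each VR to the CDS that fully contains it on the VR strand.

    The RT CDS itself is never a target.  Partial overlaps and intergenic VRs
    stay unassigned and flag the cassette.  When several CDS contain a VR
    (nested annotations) the smallest is taken.
    """
    rt_iv = cassette.anchor.cds_interval
    targets: list[Optional[Feature]] = []
    for vs, ve in cassette.vrs:
        best = None
        for f in features:
            if f.kind != "CDS":
                continue
            if (f.start, f.end) == rt_iv and f.strand == cassette.anchor.strand:
                continue
            if f.strand == cassette.vr_strand and f.start <= vs and ve <= f.end:
                if best is None or (f.end - f.start) < (best.end - best.start):
                    best = f
        targets.append(best)
    cassette.target_orfs = targets
    if any(t is None for t in targets) and "unassigned VR" not in cassette.flags:
        cassette.flags.append("unassigned VR")
    return cassette


def _subgroup_letter(n_vr: int, codes: Sequence[str]) -> str:
    """Deterministic letter for an arrangement signature.

    Signatures are enumerated by VR count first, then lexicographically over
    the 5 placement codes; index 0 (one VR, code U) is "a".
    """
    base = sum(5 ** k for k in range(1, n_vr))
    rank = 0
    for c in codes:
        rank = rank * 5 + _CODES.index(c)
    idx = base + rank
    letters = ""
    idx += 1
    while idx:
        idx, rem = divmod(idx - 1, 26)
        letters = chr(97 + rem) + letters
    return letters


def classify_structure(
    cassette: DGRCassette, parent_length: Optional[int] = None
) -> tuple[int, str]:
    """Assign the (group, subgroup) architecture of a cassette.

    Positions are evaluated in RT-coding-strand orientation ("upstream" means
    5' of the RT CDS start on that strand).  The strand test (group 4) takes
    precedence; overlap with the RT CDS marks group 3 even when the TR lies
    fully inside the CDS (flagged).
    """
    anchor = cassette.anchor
    if cassette.tr_strand not in "+-":
        raise DgrScanError("TR strand undefined; cannot classify")
    if anchor.strand == "-" and parent_length is None:
        raise InputError("parent_length required to classify a '-' strand anchor")

    def norm(iv: tuple[int, int]) -> tuple[int, int]:
        if anchor.strand == "+":
            return iv
        return (parent_length - iv[1], parent_length - iv[0])

    tr = norm(cassette.tr_interval)
    rt = norm(anchor.cds_interval)

    if cassette.tr_strand != anchor.strand:
        group = 4
    elif tr[1] > rt[0] and tr[0] < rt[1]:
        group = 3
        if rt[0] <= tr[0] and tr[1] <= rt[1] and "TR inside RT CDS" not in cassette.flags:
            cassette.flags.append("TR inside RT CDS")
    elif tr[1] <= rt[0]:
        group = 1
    else:
        group = 2

    lo_start = min(tr[0], rt[0])
    hi_end = max(tr[1], rt[1])
    first, second = sorted((tr, rt))
    codes = []
    for iv in sorted(norm(v) for v in cassette.vrs):
        if iv[1] > rt[0] and iv[0] < rt[1]:
            codes.append("O")
        elif iv[1] <= lo_start:
            codes.append("U")
        elif iv[0] >= hi_end:
            codes.append("D")
        elif iv[0] >= first[1] and iv[1] <= second[0]:
            codes.append("M")
        else:
            codes.append("X")
    subgroup = _subgroup_letter(cassette.n_vr, codes)
    cassette.group = group
    cassette.subgroup = subgroup
    return group, subgroup


def rescan_targets(
    seq: AnnotatedSequence,
    tr_seq: str,
    tr_interval: tuple[int, int],
    wildcard: str = "A",
    min_substitutions: int = 1,
) -> list[dict]:
    """Whole-record search for additional perfect wildcard-matches of a TR.

    Slides the TR over both strands of the full parent record and reports
    placements where every non-wildcard TR base matches exactly and at least
    ``min_substitutions`` wildcard positions differ — the signature of a
    distal VR beyond the standard scan window.  Placements overlapping the TR
    itself are skipped; a containing CDS is reported when one exists.
    """
    out = []
    m = len(tr_seq)
    if m == 0 or len(seq.residues) < m:
        return out
    tr_arr = np.frombuffer(tr_seq.encode(), dtype=np.uint8)
    wc, nn = ord(wildcard), ord("N")
    wild_mask = tr_arr == wc
    for strand in "+-":
        residues = seq.residues if strand == "+" else _rc(seq.residues)
        arr = np.frombuffer(residues.encode(), dtype=np.uint8)
        wins = np.lib.stride_tricks.sliding_window_view(arr, m)
        ok = (wild_mask[None, :] | (wins == tr_arr[None, :])) & (wins != nn)
        full = ok.all(axis=1)
        for p in np.flatnonzero(full):
            if strand == "+":
                iv = (int(p), int(p) + m)
            else:
                iv = (len(seq.residues) - int(p) - m, len(seq.residues) - int(p))
            if iv[0] < tr_interval[1] and iv[1] > tr_interval[0]:
                continue  # the TR itself
            window = residues[p : p + m]
            n_sub = sum(
                1 for t, v in zip(tr_seq, window) if t == wildcard and v != t
            )
            if n_sub < min_substitutions:
                continue
            cds = next(
                (
                    f
                    for f in seq.features
                    if f.kind == "CDS" and f.start <= iv[0] and iv[1] <= f.end
                ),
                None,
            )
            out.append(
                {
                    "interval": iv,
                    "strand": strand,
                    "n_substitutions": n_sub,
                    "cds_label": cds.qualifiers.get("locus_tag") if cds else None,
                }
            )
    out.sort(key=lambda r: r["interval"])
    return out


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def cassette_table(cassettes: Sequence[DGRCassette], path=None):
    """Tabulate cassettes (1-based inclusive intervals on disk)."""
    import pandas as pd

    rows = []
    for c in cassettes:
        rows.append(
            {
                "anchor": c.anchor.label,
                "group": c.group,
                "subgroup": c.subgroup,
                "n_vr": c.n_vr,
                "tr_start": c.tr_interval[0] + 1,
                "tr_end": c.tr_interval[1],
                "tr_strand": c.tr_strand,
                "vr_intervals": ";".join(f"{a + 1}-{b}" for a, b in c.vrs),
                "targets": ";".join(
                    (t.qualifiers.get("locus_tag", "?") if t else "none")
                    for t in c.target_orfs
                )
                if c.target_orfs
                else "",
                "flags": ";".join(c.flags),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "anchor", "group", "subgroup", "n_vr", "tr_start", "tr_end",
            "tr_strand", "vr_intervals", "targets", "flags",
        ],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
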