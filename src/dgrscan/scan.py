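"""Wildcard-base sliding-window repeat detection (the core DGR search).

A DGR rewrites its variable repeat (VR) with an error-prone cDNA copy of the
template repeat (TR); mutations are restricted to TR adenines.  The scanner
therefore slides a window over the RT-centred region and looks for a second
placement at which every *non-wildcard* window base matches exactly (the
wildcard base, adenine by default, is exempt).  Matching seeds are extended to
maximal length, deduplicated, and filtered by a minimum wildcard count in the
TR and a minimum number of wildcard-position substitutions in the VR.

The same machinery with the wildcard role reassigned to T uncovers "inverted"
elements whose TR/VR sit on the opposite strand from the RT gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .errors import InputError
from .io_genbank import ScanRegion

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanParams:
    """Search thresholds; the defaults are the standard search settings."""

    window_size: int = 50
    step: int = 1
    flank: int = 5000
    wildcard_base: str = "A"
    min_wildcard_in_tr: int = 10
    min_substitutions: int = 7
    scan_reverse: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 10:
            raise InputError("window_size must be >= 10")
        if self.step < 1:
            raise InputError("step must be >= 1")
        if self.min_substitutions < 1:
            raise InputError("min_substitutions must be >= 1")
        if self.min_wildcard_in_tr < self.min_substitutions:
            raise InputError("min_wildcard_in_tr must be >= min_substitutions")
        if self.wildcard_base not in "ACGT":
            raise InputError("wildcard_base must be one of A, C, G, T")
        if self.flank < 0:
            raise InputError("flank must be >= 0")


@dataclass(frozen=True)
class RepeatHit:
    """One maximal TR/VR pair.

    Intervals are 0-based half-open on the parent sequence; ``substitutions``
    lists (offset within the repeat, TR base, VR base) in the scanned (RT
    strand) orientation, so every substitution has TR base equal to the
    wildcard.  For inverted hits (wildcard T on the RT strand) the element is
    adenine-specific on the opposite strand; :meth:`on_element_strand` returns
    that representation.
    """

    parent_id: str
    tr_interval: tuple[int, int]
    vr_interval: tuple[int, int]
    length: int
    strand_relation: str  # 'same' | 'inverted'
    wildcard_base: str
    n_wildcard_tr: int
    substitutions: list[tuple[int, str, str]]
    counts_by_target: dict[str, int]
    element_strand: str = "+"
    tr_seq: str = ""
    vr_seq: str = ""
    tr_region: Optional[tuple[int, int]] = None
    vr_region: Optional[tuple[int, int]] = None

    def on_element_strand(self) -> "RepeatHit":
        """Express an inverted hit on its own (A-specific) strand."""
        if self.strand_relation != "inverted":
            return self
        n = self.length
        subs = sorted(
            (n - 1 - off, t.translate(_COMPLEMENT), v.translate(_COMPLEMENT))
            for off, t, v in self.substitutions
        )
        counts = {}
        for _, _, v in subs:
            counts[v] = counts.get(v, 0) + 1
        return replace(
            self,
            wildcard_base=self.wildcard_base.translate(_COMPLEMENT),
            substitutions=subs,
            counts_by_target=counts,
            tr_seq=revcomp(self.tr_seq) if self.tr_seq else "",
            vr_seq=revcomp(self.vr_seq) if self.vr_seq else "",
        )


# ---------------------------------------------------------------------------
# matching primitives

def _column_ok(tr_base: str, vr_base: str, wildcard: str) -> bool:
    """The single-column match rule: exact match, or TR shows the wildcard.

    N matches nothing, neither as wildcard nor as a substitution target.
    """
    if tr_base == "N" or vr_base == "N":
        return False
    if tr_base == wildcard:
        return True
    return tr_base == vr_base


def extend_match(
    residues: str,
    tr_start: int,
    vr_start: int,
    length: int,
    wildcard_base: str = "A",
) -> tuple[int, int, int]:
    """Grow a matching seed to maximal length.

    Single-position steps alternate left, then right, while the column rule
    holds at the new flanking positions, neither interval leaves the region,
    and the two intervals stay disjoint.  The result admits no further
    single-position extension on either side.
    """
    L = len(residues)
    lo = min(tr_start, vr_start)
    hi = max(tr_start, vr_start)
    gap = hi - lo  # distance between interval starts; overlap cap: length <= gap

    def can_left() -> bool:
        if lo - 1 < 0 or length >= gap:
            return False
        return _column_ok(residues[tr_start - 1], residues[vr_start - 1], wildcard_base)

    def can_right() -> bool:
        if hi + length >= L or length >= gap:
            return False
        return _column_ok(
            residues[tr_start + length], residues[vr_start + length], wildcard_base
        )

    while True:
        moved = False
        if can_left():
            tr_start -= 1
            vr_start -= 1
            lo -= 1
            hi -= 1
            length += 1
            moved = True
        if can_right():
            length += 1
            moved = True
        if not moved:
            return tr_start, vr_start, length


def _runs_at_least(ok: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True in ``ok`` with length >= min_len, as (start, len)."""
    bad = np.flatnonzero(~ok)
    bounds = np.concatenate(([-1], bad, [ok.size]))
    gaps = bounds[1:] - bounds[:-1] - 1
    keep = gaps >= min_len
    starts = bounds[:-1][keep] + 1
    return list(zip(starts.tolist(), gaps[keep].tolist()))


def _seed_exists(run_start: int, run_len: int, tr_offset: int, W: int, step: int) -> bool:
    """Is there a window start at a step multiple inside the run?

    ``tr_offset`` is added to column indices to get TR coordinates (0 when the
    TR is the left copy of the pair, d when it is the right copy).
    """
    first = run_start + tr_offset
    last = run_start + run_len - W + tr_offset
    if step == 1:
        return last >= first
    k = (-first) % step
    return first + k <= last


def scan_residues(residues: str, params: ScanParams) -> list[RepeatHit]:
    """Scan a raw residue string; hits carry local (region) coordinates.

    Runs the sliding-window search at every step increment, extends each
    matching placement to maximal length, collapses duplicates, drops pairs
    strictly contained in another pair, then applies the wildcard-count and
    substitution-count filters.
    """
    L = len(residues)
    W = params.window_size
    wc = params.wildcard_base
    if L < W:
        log.info("region of length %d shorter than window %d; nothing to scan", L, W)
        return []
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    wc_code = ord(wc)
    n_code = ord("N")

    pairs: set[tuple[int, int, int, int]] = set()
    for d in range(W, L - W + 1):
        x = arr[: L - d]
        y = arr[d:]
        eq = (x == y) & (x != n_code)
        ok_left = eq | ((x == wc_code) & (y != n_code))   # TR is the left copy
        ok_right = eq | ((y == wc_code) & (x != n_code))  # TR is the right copy
        for ok, tr_is_left in ((ok_left, True), (ok_right, False)):
            for r, l in _runs_at_least(ok, W):
                tr_off = 0 if tr_is_left else d
                if not _seed_exists(r, l, tr_off, W, params.step):
                    continue
                if l <= d:
                    # extension is never capped by overlap: the whole run is
                    # the unique maximal pair for every seed inside it
                    ta, va = (r, r + d) if tr_is_left else (r + d, r)
                    pairs.add((ta, ta + l, va, va + l))
                else:
                    # tandem-like: the overlap cap makes maximality depend on
                    # the seed; enumerate seeds and extend each one
                    first = r + ((-(r + tr_off)) % params.step)
                    for i in range(first, r + l - W + 1, params.step):
                        ta, va = (i, i + d) if tr_is_left else (i + d, i)
                        ts, vs, ln = extend_match(residues, ta, va, W, wc)
                        pairs.add((ts, ts + ln, vs, vs + ln))

    # drop pairs contained in another pair with the same alignment offset
    # (a containing pair at a different offset is a distinct alignment)
    plist = sorted(pairs)
    kept = []
    for p in plist:
        contained = any(
            q != p
            and q[2] - q[0] == p[2] - p[0]
            and q[0] <= p[0] and p[1] <= q[1]
            and q[2] <= p[2] and p[3] <= q[3]
            for q in plist
        )
        if not contained:
            kept.append(p)

    hits = []
    for ts, te, vs, ve in kept:
        tr_seq = residues[ts:te]
        vr_seq = residues[vs:ve]
        subs = [
            (k, t, v)
            for k, (t, v) in enumerate(zip(tr_seq, vr_seq))
            if t == wc and v != t
        ]
        n_wild = tr_seq.count(wc)
        if n_wild < params.min_wildcard_in_tr or len(subs) < params.min_substitutions:
            continue
        counts: dict[str, int] = {}
        for _, _, v in subs:
            counts[v] = counts.get(v, 0) + 1
        hits.append(
            RepeatHit(
                parent_id="",
                tr_interval=(ts, te),
                vr_interval=(vs, ve),
                length=te - ts,
                strand_relation="inverted" if wc == "T" else "same",
                wildcard_base=wc,
                n_wildcard_tr=n_wild,
                substitutions=subs,
                counts_by_target=counts,
                tr_seq=tr_seq,
                vr_seq=vr_seq,
                tr_region=(ts, te),
                vr_region=(vs, ve),
            )
        )
    hits.sort(key=lambda h: (h.tr_interval, h.vr_interval))
    return hits


def scan_region(region: ScanRegion, params: ScanParams = ScanParams()) -> list[RepeatHit]:
    """Run the repeat search on a scan region; hits carry parent coordinates."""
    local = scan_residues(region.residues, params)
    out = []
    for h in local:
        same = h.strand_relation == "same"
        element_strand = region.strand if same else ("-" if region.strand == "+" else "+")
        out.append(
            replace(
                h,
                parent_id=region.parent_id,
                tr_interval=region.interval_to_parent(*h.tr_region),
                vr_interval=region.interval_to_parent(*h.vr_region),
                element_strand=element_strand,
            )
        )
    out.sort(key=lambda h: (h.tr_interval, h.vr_interval))
    return out


def scan_generalized(region: ScanRegion, params: ScanParams) -> list[RepeatHit]:
    """Repeat search with the wildcard role reassigned to C, G or T.

    A hit under wildcard T on the RT-coding strand is an adenine-specific
    element on the opposite strand and is reported with
    strand_relation='inverted'; C and G hits are reported as-is.
    """
    if params.wildcard_base not in "CGT":
        raise InputError("scan_generalized expects wildcard_base in {C,G,T}")
    return scan_region(region, params)


def sweep_wildcards(
    region: ScanRegion, params: ScanParams, wildcards: Iterable[str] = "CGT"
) -> dict[str, list[RepeatHit]]:
    """Run the generalized scan for several wildcard bases."""
    return {
        w: scan_generalized(region, replace(params, wildcard_base=w))
        for w in wildcards
    }


# ---------------------------------------------------------------------------
# alignment rendering

def align_pair(hit: RepeatHit, width: int = 60) -> str:
    """Render a TR/VR pair as wrapped three-line blocks.

    The match line shows '|' for matching columns and '*' where a
    wildcard-position substitution occurred.
    """
    if not hit.tr_seq or not hit.vr_seq:
        raise InputError("hit carries no sequences; re-run the scan to align")
    if width < 1:
        raise InputError("width must be >= 1")
    sub_offsets = {off for off, _, _ in hit.substitutions}
    match = "".join("*" if i in sub_offsets else "|" for i in range(hit.length))
    header = (
        f"# TR {hit.tr_interval[0] + 1}..{hit.tr_interval[1]} "
        f"VR {hit.vr_interval[0] + 1}..{hit.vr_interval[1]} "
        f"length={hit.length} substitutions={len(hit.substitutions)} "
        f"wildcard={hit.wildcard_base} relation={hit.strand_relation}"
    )
    blocks = [header]
    for i in range(0, hit.length, width):
        blocks.append(
            "\n".join(
                (
                    f"TR  {hit.tr_seq[i:i + width]}",
                    f"    {match[i:i + width]}",
                    f"VR  {hit.vr_seq[i:i + width]}",
                )
            )
        )
    return "\n\n".join(blocks) + "\n"


def parse_alignment(text: str) -> tuple[str, str, list[tuple[int, str, str]]]:
    """Recover (tr_seq, vr_seq, substitutions) from :func:`align_pair` output."""
    tr_parts, vr_parts = [], []
    for line in text.splitlines():
        if line.startswith("TR  "):
            tr_parts.append(line[4:])
        elif line.startswith("VR  "):
            vr_parts.append(line[4:])
    tr_seq = "".join(tr_parts)
    vr_seq = "".join(vr_parts)
    subs = [
        (i, t, v) for i, (t, v) in enumerate(zip(tr_seq, vr_seq)) if t != v
    ]
    return tr_seq, vr_seq, subs
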