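"""DGR-diagnostic motif annotation for reverse-transcriptase proteins.

DGR RTs are distinguished from retroviral and group-II-intron RTs by a
(I/V/L)GxxxSQ heptamer in RT domain 4 (the "SQ motif"; rare variants swap the
final dipeptide for SP, SH, NQ, PA, AQ or VQ), a [Y/F]xDD catalytic motif in
domain 5 with two invariant aspartates, and a strongly positive (R/K-rich)
20-residue patch near the C terminus, presumably involved in template
binding.  This module locates all three by direct pattern scanning; no
multiple alignment is required.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import mean
from typing import Optional, Sequence

import pandas as pd

from .errors import InputError

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
MOTIF4_VARIANTS = ("SP", "SH", "NQ", "PA", "AQ", "VQ")
CANONICAL = "canonical-SQ"


@dataclass(frozen=True)
class YddRecord:
    offset: int
    tetramer: str
    pos1: str  # Y or F
    pos2: str  # the variable residue


@dataclass(frozen=True)
class Motif4Record:
    offset: Optional[int]
    heptamer: Optional[str]
    klass: str  # 'canonical-SQ' | variant code | 'other' | 'absent'


@dataclass(frozen=True)
class ChargeRecord:
    offset: Optional[int]
    count: Optional[int]       # R+K residues in the best 20-aa window
    fraction: Optional[float]
    positive: bool             # count >= 10
    absent: bool = False


@dataclass(frozen=True)
class MotifReport:
    rt_label: str
    rt_length: int
    ydd: Optional[YddRecord]
    motif4: Motif4Record
    charge_patch: Optional[ChargeRecord]


def find_ydd(protein: str) -> Optional[YddRecord]:
    """First [Y/F]xDD tetramer scanning N->C, or None.

    The x position admits any standard residue; X never matches.
    """
    if not protein:
        raise InputError("empty protein sequence")
    for i in range(len(protein) - 3):
        a, b, c, d = protein[i : i + 4]
        if a in "YF" and b in AA20 and c == "D" and d == "D":
            return YddRecord(offset=i, tetramer=protein[i : i + 4], pos1=a, pos2=b)
    return None


def _heptamers(protein: str, lo: int, hi: int):
    """Yield (offset, heptamer) for [ILV]Gxxxxx heptamers starting in [lo,hi)."""
    for i in range(max(lo, 0), min(hi, len(protein) - 6)):
        hep = protein[i : i + 7]
        if hep[0] in "ILV" and hep[1] == "G" and all(ch in AA20 for ch in hep):
            yield i, hep


def classify_dipeptide(dipep: str) -> str:
    if dipep == "SQ":
        return CANONICAL
    if dipep in MOTIF4_VARIANTS:
        return dipep
    return "other"


def find_motif4(protein: str, ydd_offset: Optional[int] = None) -> Motif4Record:
    """Locate the domain-4 heptamer and classify its final dipeptide.

    When the catalytic YxDD is known, only heptamers ending within the 100
    residues preceding it are considered and the one nearest the YxDD wins;
    without it the whole protein is scanned and the first heptamer is taken.
    """
    if not protein:
        raise InputError("empty protein sequence")
    if ydd_offset is not None:
        cands = [
            (i, hep)
            for i, hep in _heptamers(protein, ydd_offset - 100, ydd_offset - 6)
            if i + 7 <= ydd_offset
        ]
        pick = cands[-1] if cands else None  # nearest to the YxDD
    else:
        pick = next(_heptamers(protein, 0, len(protein)), None)
    if pick is None:
        return Motif4Record(offset=None, heptamer=None, klass="absent")
    i, hep = pick
    return Motif4Record(offset=i, heptamer=hep, klass=classify_dipeptide(hep[5:7]))


def charge_patch(protein: str, ydd_offset: int) -> ChargeRecord:
    """Best 20-aa window downstream of the YxDD by R+K count.

    Ties break toward the smallest offset; the "positive patch" flag fires at
    10 or more R/K residues (50 %).  A tail shorter than 20 aa yields an
    absent record.
    """
    if not protein:
        raise InputError("empty protein sequence")
    if len(protein) - ydd_offset < 20:
        return ChargeRecord(None, None, None, positive=False, absent=True)
    best_count, best_off = -1, None
    for i in range(ydd_offset, len(protein) - 19):
        c = sum(1 for ch in protein[i : i + 20] if ch in "RK")
        if c > best_count:
            best_count, best_off = c, i
    return ChargeRecord(
        offset=best_off,
        count=best_count,
        fraction=best_count / 20.0,
        positive=best_count >= 10,
    )


def analyze_protein(label: str, protein: str) -> MotifReport:
    """Full motif report for one RT protein."""
    protein = protein.upper().rstrip("*")
    ydd = find_ydd(protein)
    motif4 = find_motif4(protein, ydd.offset if ydd else None)
    patch = charge_patch(protein, ydd.offset) if ydd else None
    return MotifReport(
        rt_label=label,
        rt_length=len(protein),
        ydd=ydd,
        motif4=motif4,
        charge_patch=patch,
    )


def summarize_rts(reports: Sequence[MotifReport]) -> dict:
    """Length statistics, canonical-SQ prevalence, and YxDD residue spectrum."""
    if not reports:
        raise InputError("no motif reports to summarize")
    lengths = [r.rt_length for r in reports]
    n = len(reports)
    return {
        "n": n,
        "length_min": min(lengths),
        "length_max": max(lengths),
        "length_mean": mean(lengths),
        "fraction_canonical_sq": sum(r.motif4.klass == CANONICAL for r in reports) / n,
        "fraction_ydd_found": sum(r.ydd is not None for r in reports) / n,
        "ydd_pos1_counts": dict(Counter(r.ydd.pos1 for r in reports if r.ydd)),
        "ydd_pos2_counts": dict(Counter(r.ydd.pos2 for r in reports if r.ydd)),
        "motif4_class_counts": dict(Counter(r.motif4.klass for r in reports)),
    }


def report_table(reports: Sequence[MotifReport], path=None) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "rt_label": r.rt_label,
                "rt_length": r.rt_length,
                "ydd_offset": r.ydd.offset + 1 if r.ydd else "",
                "ydd": r.ydd.tetramer if r.ydd else "absent",
                "ydd_pos2": r.ydd.pos2 if r.ydd else "",
                "motif4_offset": r.motif4.offset + 1 if r.motif4.offset is not None else "",
                "motif4": r.motif4.heptamer or "absent",
                "motif4_class": r.motif4.klass,
                "charge_rk_count": r.charge_patch.count
                if r.charge_patch and not r.charge_patch.absent
                else "",
                "charge_positive": bool(r.charge_patch and r.charge_patch.positive),
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
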