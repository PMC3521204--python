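"""Reading and writing annotated DNA and the RT anchor / hit tables.

Internal coordinates are 0-based half-open throughout; every on-disk format
(GenBank, anchor TSV, hit TSV, truth TSV) is 1-based inclusive, matching the
usual bioinformatics convention split.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, InputError, ParseError

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class Feature:
    """One annotation on a sequence (0-based half-open interval)."""

    kind: str
    start: int
    end: int
    strand: str  # '+' or '-'
    qualifiers: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AnnotatedSequence:
    """A DNA record: residues over {A,C,G,T,N} plus its features."""

    id: str
    residues: str
    features: list[Feature] = field(default_factory=list)
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"record {self.id!r} has an empty sequence")
        for f in self.features:
            if not (0 <= f.start <= f.end <= len(self.residues)):
                raise CoordinateError(
                    f"feature {f.kind} [{f.start},{f.end}) outside record "
                    f"{self.id!r} of length {len(self.residues)}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RTAnchor:
    """An RT gene's CDS location on a parent sequence; the scan origin."""

    sequence_id: str
    cds_interval: tuple[int, int]  # 0-based half-open
    strand: str
    label: str
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        s, e = self.cds_interval
        if e - s < 3:
            raise InputError(f"anchor {self.label!r}: CDS shorter than one codon")
        if self.strand not in "+-":
            raise InputError(f"anchor {self.label!r}: strand must be + or -")


@dataclass(frozen=True)
class ScanRegion:
    """The RT-centred subsequence, oriented on the RT-coding strand.

    ``residues`` equal the parent slice when the anchor is on '+', and its
    reverse complement when the anchor is on '-'; the affine offset map
    converts region positions back to parent positions exactly.
    """

    anchor: RTAnchor
    parent_id: str
    parent_start: int  # interval on parent, 0-based half-open
    parent_end: int
    parent_length: int
    residues: str

    @property
    def strand(self) -> str:
        return self.anchor.strand

    def __len__(self) -> int:
        return len(self.residues)

    def to_parent(self, i: int) -> int:
        """Map a region position to the parent coordinate."""
        if not (0 <= i < len(self.residues)):
            raise CoordinateError(f"region position {i} out of range")
        if self.strand == "+":
            return self.parent_start + i
        return self.parent_end - 1 - i

    def to_region(self, p: int) -> int:
        """Inverse of :meth:`to_parent`."""
        if not (self.parent_start <= p < self.parent_end):
            raise CoordinateError(f"parent position {p} outside region")
        if self.strand == "+":
            return p - self.parent_start
        return self.parent_end - 1 - p

    def interval_to_parent(self, a: int, b: int) -> tuple[int, int]:
        """Map a half-open region interval [a,b) to parent coordinates."""
        if not (0 <= a < b <= len(self.residues)):
            raise CoordinateError(f"region interval [{a},{b}) out of range")
        if self.strand == "+":
            return (self.parent_start + a, self.parent_start + b)
        return (self.parent_end - b, self.parent_end - a)


def _clean_residues(record_id: str, raw: str) -> str:
    seq = raw.upper()
    n_bad = len(_NON_ACGTN.findall(seq))
    if n_bad:
        log.warning(
            "record %s: %d non-ACGTN characters mapped to N", record_id, n_bad
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def _strand_char(strand: Optional[int]) -> str:
    return "-" if strand == -1 else "+"


def _from_seqrecord(rec: SeqRecord) -> AnnotatedSequence:
    features = []
    for f in rec.features:
        if f.location is None:
            continue
        quals = {k: (v[0] if isinstance(v, list) and v else v)
                 for k, v in f.qualifiers.items()}
        features.append(
            Feature(
                kind=f.type,
                start=int(f.location.start),
                end=int(f.location.end),
                strand=_strand_char(f.location.strand),
                qualifiers=quals,
            )
        )
    source = {"description": rec.description}
    organism = rec.annotations.get("organism") if rec.annotations else None
    if organism:
        source["organism"] = organism
    return AnnotatedSequence(
        id=rec.id,
        residues=_clean_residues(rec.id, str(rec.seq)),
        features=features,
        source=source,
    )


def read_sequences(path, format: str = "genbank") -> list[AnnotatedSequence]:
    """Read a GenBank or FASTA file into :class:`AnnotatedSequence` records."""
    if format not in ("genbank", "fasta"):
        raise InputError(f"unsupported format {format!r}")
    try:
        handle = open(path)
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    records = []
    with handle:
        try:
            for rec in SeqIO.parse(handle, format):
                records.append(_from_seqrecord(rec))
        except ValueError as exc:
            where = records[-1].id if records else "first record"
            raise ParseError(
                f"malformed {format} in {path} after {where}: {exc}"
            ) from exc
    return records


def find_rt_anchors(
    seq: AnnotatedSequence,
    pattern: str = r"reverse[ _-]?transcriptase|\bRT\b|retron",
) -> list[RTAnchor]:
    """Collect RT anchors from CDS features whose qualifiers match ``pattern``.

    The product, gene, note and label qualifiers are searched
    case-insensitively.  Labels come from locus_tag/label or are synthesised.
    """
    rx = re.compile(pattern, re.IGNORECASE)
    anchors = []
    for i, f in enumerate(seq.features):
        if f.kind != "CDS":
            continue
        text = " ".join(
            str(f.qualifiers.get(k, ""))
            for k in ("product", "gene", "note", "label", "locus_tag")
        )
        if rx.search(text):
            label = (
                f.qualifiers.get("locus_tag")
                or f.qualifiers.get("label")
                or f"{seq.id}_rt{i}"
            )
            anchors.append(
                RTAnchor(
                    sequence_id=seq.id,
                    cds_interval=(f.start, f.end),
                    strand=f.strand,
                    label=str(label),
                    protein=f.qualifiers.get("translation"),
                )
            )
    return anchors


def read_rt_table(path) -> list[RTAnchor]:
    """Read a TSV anchor table (sequence_id, start, end, strand, label).

    Coordinates on disk are 1-based inclusive; strands are '+'/'-'.  Blank
    lines and '#' comments are skipped, as is an optional header row.
    """
    anchors: list[RTAnchor] = []
    seen_labels: set[str] = set()
    try:
        lines = open(path).read().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split()
        if cols[:2] == ["sequence_id", "start"]:
            continue  # header
        if len(cols) < 5:
            raise ParseError(f"{path} line {lineno}: expected 5 columns, got {len(cols)}")
        seq_id, s_raw, e_raw, strand, label = cols[:5]
        try:
            start1, end1 = int(s_raw), int(e_raw)
        except ValueError:
            raise ParseError(f"{path} line {lineno}: non-integer coordinate") from None
        if start1 > end1:
            raise ParseError(f"{path} line {lineno}: start > end")
        if strand not in "+-":
            raise ParseError(f"{path} line {lineno}: bad strand {strand!r}")
        if label in seen_labels:
            raise ParseError(f"{path} line {lineno}: duplicate label {label!r}")
        seen_labels.add(label)
        anchors.append(
            RTAnchor(
                sequence_id=seq_id,
                cds_interval=(start1 - 1, end1),
                strand=strand,
                label=label,
            )
        )
    return anchors


def extract_region(
    seq: AnnotatedSequence, anchor: RTAnchor, flank: int = 5000
) -> ScanRegion:
    """Cut the RT-centred scan window (CDS plus ``flank`` nt on each side).

    The result is oriented on the RT-coding strand: for a '-' anchor the
    region residues are the reverse complement of the parent slice.
    """
    if flank < 0:
        raise InputError("flank must be >= 0")
    if anchor.sequence_id != seq.id:
        raise CoordinateError(
            f"anchor {anchor.label!r} refers to {anchor.sequence_id!r}, not {seq.id!r}"
        )
    cs, ce = anchor.cds_interval
    if not (0 <= cs < ce <= len(seq)):
        raise CoordinateError(
            f"anchor {anchor.label!r} CDS [{cs},{ce}) outside sequence of length {len(seq)}"
        )
    start = max(0, cs - flank)
    end = min(len(seq), ce + flank)
    piece = seq.residues[start:end]
    if anchor.strand == "-":
        piece = str(Seq(piece).reverse_complement())
    return ScanRegion(
        anchor=anchor,
        parent_id=seq.id,
        parent_start=start,
        parent_end=end,
        parent_length=len(seq),
        residues=piece,
    )


def _region_feature(
    region: ScanRegion, parent_interval: tuple[int, int], element_strand: str
) -> tuple[int, int, int]:
    """Convert a parent interval back to region coordinates + Biopython strand."""
    a, b = parent_interval
    if not (region.parent_start <= a < b <= region.parent_end):
        raise CoordinateError(
            f"interval [{a},{b}) outside region [{region.parent_start},{region.parent_end})"
        )
    if region.strand == "+":
        ra, rb = a - region.parent_start, b - region.parent_start
    else:
        ra, rb = region.parent_end - b, region.parent_end - a
    strand = 1 if element_strand == region.strand else -1
    return ra, rb, strand


def write_annotation(region: ScanRegion, hits: Sequence, cassette=None, path=None):
    """Write the region as a GenBank flat file with RT/TR/VR features.

    The RT CDS is written as a CDS feature; the TR and each VR become
    misc_features carrying /label ("TR", "VR1", ...) and a /note with the
    adenine and substitution counts, so the file displays sensibly in
    feature-oriented viewers.  Returns the written :class:`SeqRecord`.
    """
    rec = SeqRecord(
        Seq(region.residues),
        id=f"{region.parent_id}",
        name=re.sub(r"\W", "", region.anchor.label)[:16] or "region",
        description=(
            f"RT-centred scan region {region.parent_id}:"
            f"{region.parent_start + 1}-{region.parent_end} ({region.strand})"
        ),
        annotations={"molecule_type": "DNA"},
    )
    ra, rb, _ = _region_feature(region, region.anchor.cds_interval, region.strand)
    quals = {"locus_tag": [region.anchor.label], "product": ["reverse transcriptase"]}
    if region.anchor.protein:
        quals["translation"] = [region.anchor.protein]
    rec.features.append(
        SeqFeature(FeatureLocation(ra, rb, strand=1), type="CDS", qualifiers=quals)
    )

    tr_intervals: list[tuple[int, int]] = []
    vr_entries = []  # (parent interval, strand, hit)
    for h in hits:
        if tuple(h.tr_interval) not in tr_intervals:
            tr_intervals.append(tuple(h.tr_interval))
        vr_entries.append((tuple(h.vr_interval), h.element_strand, h))
    tr_intervals.sort()
    vr_entries.sort(key=lambda t: t[0])

    for i, iv in enumerate(tr_intervals):
        # the matching hit supplies strand and counts
        h = next(h for h in hits if tuple(h.tr_interval) == iv)
        ra, rb, st = _region_feature(region, iv, h.element_strand)
        label = "TR" if len(tr_intervals) == 1 else f"TR{i + 1}"
        note = f"adenines={h.n_wildcard_tr};wildcard={h.wildcard_base}"
        rec.features.append(
            SeqFeature(
                FeatureLocation(ra, rb, strand=st),
                type="misc_feature",
                qualifiers={"label": [label], "note": [note]},
            )
        )
    for i, (iv, strand, h) in enumerate(vr_entries):
        ra, rb, st = _region_feature(region, iv, strand)
        targets = ",".join(f"{b}:{n}" for b, n in sorted(h.counts_by_target.items()))
        note = (
            f"substitutions={len(h.substitutions)};adenines={h.n_wildcard_tr};"
            f"targets={targets}"
        )
        rec.features.append(
            SeqFeature(
                FeatureLocation(ra, rb, strand=st),
                type="misc_feature",
                qualifiers={"label": [f"VR{i + 1}"], "note": [note]},
            )
        )
    if cassette is not None and cassette.group is not None:
        lo = min(cassette.tr_interval[0], *(v[0] for v in cassette.vrs))
        hi = max(cassette.tr_interval[1], *(v[1] for v in cassette.vrs))
        lo = min(lo, region.anchor.cds_interval[0])
        hi = max(hi, region.anchor.cds_interval[1])
        ra, rb, _ = _region_feature(region, (lo, hi), region.strand)
        rec.features.append(
            SeqFeature(
                FeatureLocation(ra, rb, strand=1),
                type="misc_feature",
                qualifiers={"label": [f"DGR_group_{cassette.group}{cassette.subgroup}"]},
            )
        )
    rec.features.sort(key=lambda f: int(f.location.start))
    if path is not None:
        with open(path, "w") as out:
            SeqIO.write([rec], out, "genbank")
    return rec


def to_seqrecord(seq: AnnotatedSequence) -> SeqRecord:
    """Convert an :class:`AnnotatedSequence` to a Biopython SeqRecord."""
    rec = SeqRecord(
        Seq(seq.residues),
        id=seq.id,
        name=re.sub(r"\W", "", seq.id)[:16] or "seq",
        description=seq.source.get("description", ""),
        annotations={"molecule_type": "DNA"},
    )
    if "organism" in seq.source:
        rec.annotations["organism"] = seq.source["organism"]
        rec.annotations["source"] = seq.source["organism"]
    for f in seq.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                type=f.kind,
                qualifiers={k: [str(v)] for k, v in f.qualifiers.items()},
            )
        )
    return rec


def write_genbank(seq: AnnotatedSequence, path) -> None:
    with open(path, "w") as out:
        SeqIO.write([to_seqrecord(seq)], out, "genbank")


# ---------------------------------------------------------------------------
# hit tables

_HIT_COLUMNS = [
    "parent_id", "anchor", "tr_start", "tr_end", "vr_start", "vr_end",
    "length", "element_strand", "strand_relation", "wildcard",
    "n_wildcard_tr", "n_substitutions", "sub_to_A", "sub_to_C", "sub_to_G",
    "sub_to_T", "substitutions",
]


def write_hit_table(hits: Iterable, path, anchors: Optional[Iterable[str]] = None):
    """Write one row per hit; intervals on disk are 1-based inclusive."""
    hits = list(hits)
    labels = list(anchors) if anchors is not None else [""] * len(hits)
    rows = []
    for h, lab in zip(hits, labels):
        subs = "|".join(f"{off + 1}:{t}>{v}" for off, t, v in h.substitutions)
        counts = {f"sub_to_{b}": h.counts_by_target.get(b, 0) for b in "ACGT"}
        rows.append(
            {
                "parent_id": h.parent_id,
                "anchor": lab,
                "tr_start": h.tr_interval[0] + 1,
                "tr_end": h.tr_interval[1],
                "vr_start": h.vr_interval[0] + 1,
                "vr_end": h.vr_interval[1],
                "length": h.length,
                "element_strand": h.element_strand,
                "strand_relation": h.strand_relation,
                "wildcard": h.wildcard_base,
                "n_wildcard_tr": h.n_wildcard_tr,
                "n_substitutions": len(h.substitutions),
                **counts,
                "substitutions": subs,
            }
        )
    df = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_hit_table(path) -> list:
    """Read a hit TSV back into lightweight :class:`RepeatHit` objects."""
    from .scan import RepeatHit  # local import to avoid a cycle

    try:
        df = pd.read_csv(path, sep="\t", dtype={"substitutions": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse hit table {path}: {exc}") from exc
    hits = []
    for _, row in df.iterrows():
        subs = []
        cell = row.get("substitutions")
        if isinstance(cell, str) and cell:
            for item in cell.split("|"):
                off, change = item.split(":")
                t, v = change.split(">")
                subs.append((int(off) - 1, t, v))
        counts = {b: int(row[f"sub_to_{b}"]) for b in "ACGT" if row[f"sub_to_{b}"]}
        hits.append(
            RepeatHit(
                parent_id=str(row["parent_id"]),
                tr_interval=(int(row["tr_start"]) - 1, int(row["tr_end"])),
                vr_interval=(int(row["vr_start"]) - 1, int(row["vr_end"])),
                length=int(row["length"]),
                strand_relation=str(row["strand_relation"]),
                wildcard_base=str(row["wildcard"]),
                n_wildcard_tr=int(row["n_wildcard_tr"]),
                substitutions=subs,
                counts_by_target=counts,
                element_strand=str(row["element_strand"]),
            )
        )
    return hits
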