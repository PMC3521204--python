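"""Synthetic bacterial contigs with planted DGR cassettes and decoy repeats.

The generator emulates the sequence context the scanner is designed for: an
i.i.d. background of configurable GC content, an RT ORF whose protein carries
the diagnostic motifs, a template repeat with a chosen adenine count, one or
more variable repeats differing from the TR only at adenine positions
(substitution targets drawn from a configurable C/G/T bias), target ORFs
containing the VRs, and decoy repeats that must NOT be reported (exact
duplications, low-substitution repeats, repeats with non-adenine mismatches,
and short low-complexity tracts).  Every planted interval is returned in a
machine-readable truth table.

Two conventions make planted coordinates exactly recoverable: a deliberately
mismatching flank base is written immediately outside each repeat copy (so
maximal extension stops exactly at the planted boundary instead of drifting
into background by chance), and for multi-VR cassettes the substitution
draws are rejected-and-redrawn until no two VRs share a window-length
conflict-free stretch (so VR-vs-VR comparisons can never seed a hit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import InputError, SizingError
from .io_genbank import AnnotatedSequence, Feature, RTAnchor

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CODON_TABLE = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "N": ("AAT", "AAC"),
    "D": ("GAT", "GAC"),
    "C": ("TGT", "TGC"),
    "Q": ("CAA", "CAG"),
    "E": ("GAA", "GAG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "K": ("AAA", "AAG"),
    "M": ("ATG",),
    "F": ("TTT", "TTC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
}
_NONSTOP_CODONS = tuple(c for codons in _CODON_TABLE.values() for c in codons)

DECOY_KINDS = (
    "exact_duplicate",
    "low_substitution",
    "non_wildcard_mismatch",
    "homopolymer",
)

_TRUTH_COLUMNS = [
    "name", "kind", "start", "end", "strand", "length", "n_adenines",
    "n_substitutions", "substitution_offsets", "detectable_default",
    "detectable_inverted", "seed",
]


@dataclass(frozen=True)
class PlantSpec:
    """Everything needed to build one synthetic contig, reproducibly."""

    seed: int
    background_length: int = 12000
    gc_fraction: float = 0.5
    tr_length: int = 110
    n_adenines_tr: int = 30
    n_vr: int = 1
    substitutions_per_vr: Union[int, tuple[int, int]] = 15
    substitution_bias: Mapping[str, float] = field(
        default_factory=lambda: {"C": 1.0, "G": 3.0, "T": 2.0}
    )
    arrangement_group: int = 1
    vr_placements: Optional[tuple[str, ...]] = None
    rt_motif_profile: str = "canonical"
    rt_strand: str = "+"
    vr_intergenic: tuple[int, ...] = ()
    decoys: tuple[str, ...] = DECOY_KINDS
    low_substitution_count: int = 6
    non_wildcard_mismatches: int = 5
    homopolymer_length: int = 24
    include_element: bool = True
    window_guard: int = 50  # no VR pair may share a conflict-free run this long
    group3_overlap: int = 30

    def __post_init__(self) -> None:
        if self.n_adenines_tr > self.tr_length:
            raise InputError("n_adenines_tr cannot exceed tr_length")
        lo, hi = self.substitution_range
        if hi > self.n_adenines_tr:
            raise InputError("substitutions_per_vr cannot exceed n_adenines_tr")
        if lo < 0:
            raise InputError("substitutions_per_vr must be >= 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise InputError("gc_fraction must lie in [0,1]")
        if self.arrangement_group not in (1, 2, 3, 4):
            raise InputError("arrangement_group must be 1..4")
        if self.rt_strand not in "+-":
            raise InputError("rt_strand must be + or -")
        if self.include_element and self.n_vr < 1:
            raise InputError("a planted element needs at least one VR")
        if self.include_element and self.n_vr > len(VR_BREAKERS):
            raise InputError(
                f"at most {len(VR_BREAKERS)} VRs are supported (one boundary "
                "breaker each)"
            )
        for d in self.decoys:
            if d not in DECOY_KINDS:
                raise InputError(f"unknown decoy kind {d!r}")
        if not 1 <= self.low_substitution_count <= 6:
            raise InputError(
                "low_substitution_count must be 1..6 (7+ would be a real hit)"
            )
        if not 1 <= self.non_wildcard_mismatches <= 8:
            raise InputError(
                "non_wildcard_mismatches must be 1..8 to keep the decoy inert"
            )
        if self.vr_placements is not None and len(self.vr_placements) != self.n_vr:
            raise InputError("vr_placements must give one code per VR")

    @property
    def substitution_range(self) -> tuple[int, int]:
        if isinstance(self.substitutions_per_vr, int):
            return (self.substitutions_per_vr, self.substitutions_per_vr)
        lo, hi = self.substitutions_per_vr
        return (int(lo), int(hi))

    @classmethod
    def decoys_only(cls, seed: int, **kwargs) -> "PlantSpec":
        """A contig with the RT anchor and decoys but no real TR/VR element."""
        kwargs.setdefault("n_vr", 1)  # ignored
        return cls(seed=seed, include_element=False, **kwargs)


# ---------------------------------------------------------------------------
# low-level sequence builders

def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NONSTOP_CODONS, size=n))


def _make_tr(rng: np.random.Generator, length: int, n_a: int, gc: float) -> str:
    """A repeat template with exactly ``n_a`` adenines."""
    a_pos = set(rng.choice(length, size=n_a, replace=False).tolist())
    non_a = "CGT"
    gcw = np.array([gc / 2, gc / 2, (1 - gc) / 2])
    gcw = gcw / gcw.sum()
    out = []
    for i in range(length):
        if i in a_pos:
            out.append("A")
        else:
            out.append(non_a[int(rng.choice(3, p=gcw))])
    return "".join(out)


def _mutate_tr(
    tr: str,
    rng: np.random.Generator,
    k: int,
    bias: Mapping[str, float],
) -> tuple[str, list[int], list[str]]:
    """Copy the TR with exactly k adenine-position substitutions."""
    a_positions = [i for i, b in enumerate(tr) if b == "A"]
    if k > len(a_positions):
        raise InputError("more substitutions requested than TR adenines")
    chosen = sorted(rng.choice(a_positions, size=k, replace=False).tolist())
    bases = sorted(b for b in bias if b in "CGT")
    w = np.array([float(bias[b]) for b in bases])
    w = w / w.sum()
    vr = list(tr)
    targets = []
    for p in chosen:
        t = bases[int(rng.choice(len(bases), p=w))]
        vr[p] = t
        targets.append(t)
    return "".join(vr), chosen, targets


def _channel_runs(x: str, y: str, wildcard: str):
    """Yield (length, visible substitutions) per maximal clean run of ``x``
    as template against ``y``.

    A column is clean when ``x`` shows the wildcard or the bases match; a
    visible substitution is a clean column where they differ.
    """
    cur = vis = 0
    for a, b in zip(x, y):
        if a == wildcard or a == b:
            cur += 1
            if a == wildcard and b != a:
                vis += 1
        else:
            if cur:
                yield cur, vis
            cur = vis = 0
    if cur:
        yield cur, vis


# Flank guards written immediately outside each planted repeat copy.  The
# pair of columns blocks maximal extension under every wildcard: the first
# column (C against G) fails unless the wildcard equals the template-side
# base, and the second (T against A) then fails for that wildcard too, so
# extension beyond a planted boundary is at most one column (C/G channels)
# and zero columns in the adenine and inverted (T) channels.
TR_GUARD = ("TC", "CT")
VR_GUARD = ("AG", "GA")

# Distinct VR copies share the same guard bases, so a zero-shift VR-vs-VR
# comparison passes straight through them.  Each VR therefore also gets a
# 4 nt "breaker" outside its guards.  The four breakers pairwise disagree in
# a C/G column (which blocks the A and T wildcard channels) and in an A/T
# column (which blocks C and G), so any VR-vs-VR clean run dies within four
# columns of the planted boundary — before it can reach random context.
VR_BREAKERS = ("CCAA", "CGAT", "GCTA", "GGTT")


def _pad(guards: tuple[str, str], seq: str) -> str:
    return guards[0] + seq + guards[1]


def _vr_context(index: int, vr: str) -> str:
    """A VR with its full planted boundary context (guards + breakers)."""
    b = VR_BREAKERS[index]
    return b[::-1] + VR_GUARD[0] + vr + VR_GUARD[1] + b


def _pair_inert(x: str, y: str, window: int, skip: str = "") -> bool:
    """Can the (x as TR, y as VR) comparison never yield a default hit?

    True when, for every wildcard channel not in ``skip``, no single maximal
    clean run both reaches the window size (so a seed exists) and shows at
    least 7 visible substitutions (so the default min_substitutions filter
    would pass).  A reported hit is exactly one maximal clean run, so the
    per-run accounting mirrors the scanner.  This is the structural guarantee
    behind "non-intended wildcard sweeps report nothing on planted elements".
    """
    for w in "ACGT":
        if w in skip:
            continue
        if any(r >= window and v >= 7 for r, v in _channel_runs(x, y, w)):
            return False
    return True


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# RT protein synthesis

def _sanitize_protein(
    prot: list[str],
    planted_ydd: Optional[int],
    planted_m4: Optional[int],
) -> None:
    """Remove accidental motif matches so the planted ones are unambiguous.

    Unplanted [Y/F]xDD tetramers lose their second aspartate; competing
    [ILV]G pairs in the 100 residues before the YxDD lose the glycine.
    Replacements use W, which participates in no pattern, and the pass loops
    to a fixed point.
    """
    for _ in range(10):
        changed = False
        for i in range(len(prot) - 3):
            if i == planted_ydd:
                continue
            if prot[i] in "YF" and prot[i + 2] == "D" and prot[i + 3] == "D":
                prot[i + 3] = "W"
                changed = True
        if planted_ydd is not None:
            lo = max(0, planted_ydd - 100)
            for i in range(lo, planted_ydd - 1):
                if i == planted_m4:
                    continue
                if prot[i] in "ILV" and prot[i + 1] == "G":
                    prot[i + 1] = "W"
                    changed = True
        if not changed:
            return


def make_rt_protein(
    profile: str, seed: Union[int, np.random.Generator]
) -> tuple[str, dict]:
    """Synthesise an RT-like protein embedding the requested motif content.

    ``profile`` is 'canonical', a variant dipeptide code (SP/SH/NQ/PA/AQ/VQ,
    optionally written 'variant:SP'), 'no-motif', or 'truncated' (the chain
    stops before the catalytic YxDD).  Returns (protein, metadata) where the
    metadata records the planted offsets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = profile.replace("variant:", "").strip()
    known = {"canonical", "no-motif", "truncated"} | set(
        ("SP", "SH", "NQ", "PA", "AQ", "VQ")
    )
    if profile not in known:
        raise InputError(f"unknown RT motif profile {profile!r}")

    L = int(rng.integers(260, 528))
    prot = list(rng.choice(list(AA_ALPHABET), size=L))
    prot[0] = "M"

    ydd_pos = int(rng.integers(120, L - 60))
    spacer = int(rng.integers(60, 91))
    m4_pos = ydd_pos - spacer

    pos1 = str(rng.choice(["Y", "F"], p=[0.86, 0.14]))
    pos2 = str(rng.choice(["M", "V", "A", "C"], p=[0.53, 0.33, 0.07, 0.07]))
    prot[ydd_pos : ydd_pos + 4] = [pos1, pos2, "D", "D"]

    meta: dict = {"length": L, "profile": profile}
    if profile in ("canonical",) or profile in ("SP", "SH", "NQ", "PA", "AQ", "VQ"):
        dipep = "SQ" if profile == "canonical" else profile
        xxx = rng.choice([a for a in AA_ALPHABET if a != "G"], size=3)
        prot[m4_pos : m4_pos + 7] = [str(rng.choice(list("ILV"))), "G", *xxx, *dipep]
        meta["motif4_offset"] = m4_pos
        planted_m4 = m4_pos
    else:
        planted_m4 = None

    # positively charged C-terminal patch: 12 R/K in a 20-aa window
    cp = L - 45 + int(rng.integers(0, 8))
    rk_slots = rng.choice(20, size=12, replace=False)
    window = list(rng.choice([a for a in AA_ALPHABET if a not in "RK"], size=20))
    for s in rk_slots:
        window[s] = str(rng.choice(["R", "K"]))
    prot[cp : cp + 20] = window
    meta["charge_patch_offset"] = cp

    if profile == "truncated":
        cut = ydd_pos - int(rng.integers(5, 30))
        prot = prot[:cut]
        _sanitize_protein(prot, planted_ydd=None, planted_m4=None)
        meta["truncated_at"] = cut
        return "".join(prot), meta

    meta["ydd_offset"] = ydd_pos
    _sanitize_protein(prot, planted_ydd=ydd_pos, planted_m4=planted_m4)
    return "".join(prot), meta


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    nt = []
    for aa in protein:
        codons = _CODON_TABLE.get(aa)
        if codons is None:
            raise InputError(f"cannot reverse-translate residue {aa!r}")
        nt.append(str(rng.choice(codons)))
    nt.append("TAA")
    return "".join(nt)


# ---------------------------------------------------------------------------
# genome assembly

class _Contig:
    """Cursor-based writer over a random background."""

    def __init__(self, spec: PlantSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.chars = list(_rand_bases(rng, spec.background_length, spec.gc_fraction))
        self.cursor = 300

    def _gap(self) -> int:
        return int(self.rng.integers(150, 400))

    def place(self, block: str, strand: str = "+") -> tuple[int, int]:
        """Write ``block`` (reverse-complemented when strand '-') at the cursor."""
        s = self.cursor
        e = s + len(block)
        if e > self.spec.background_length - 200:
            raise SizingError(
                f"spec does not fit: needs > {e + 200} nt, background is "
                f"{self.spec.background_length}"
            )
        written = block if strand == "+" else revcomp(block)
        self.chars[s:e] = list(written)
        self.cursor = e + self._gap()
        return s, e

    @staticmethod
    def map_sub(s: int, e: int, strand: str, a: int, b: int) -> tuple[int, int]:
        """Map a block-frame subinterval [a,b) to contig coordinates."""
        if strand == "+":
            return (s + a, s + b)
        return (s + (e - s) - b, s + (e - s) - a)

    def sequence(self) -> str:
        return "".join(self.chars)


def _default_placements(spec: PlantSpec) -> tuple[str, ...]:
    if spec.vr_placements is not None:
        return spec.vr_placements
    return ("U",) * spec.n_vr if spec.arrangement_group == 1 else ("D",) * spec.n_vr


def _build_vrs(tr: str, rng: np.random.Generator, spec: PlantSpec):
    """Draw every VR, redrawing until no VR pair could seed a scan hit."""
    lo, hi = spec.substitution_range
    vrs = []
    for _ in range(spec.n_vr):
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        for attempt in range(500):
            vr, offs, targets = _mutate_tr(tr, rng, k, spec.substitution_bias)
            # evaluate inertness on copies padded with their real boundary
            # context, so guard/breaker leakage is accounted for exactly
            # N columns align the TR context with the 6-column VR context;
            # they are never reached, because the TR/VR guard pair blocks
            # every wildcard channel within its two columns
            tr_p = "NNNN" + _pad(TR_GUARD, tr) + "NNNN"
            vr_p = _vr_context(len(vrs), vr)
            prevs = [_vr_context(i, p) for i, (p, _, _) in enumerate(vrs)]
            ok = (
                # the TR-as-template wildcard-A channel is the intended detection
                _pair_inert(tr_p, vr_p, spec.window_guard, skip="A")
                and _pair_inert(vr_p, tr_p, spec.window_guard)
                and all(
                    _pair_inert(prev_p, vr_p, spec.window_guard)
                    and _pair_inert(vr_p, prev_p, spec.window_guard)
                    for prev_p in prevs
                )
            )
            if ok:
                vrs.append((vr, offs, targets))
                break
        else:
            raise SizingError("could not draw mutually inert VR copies")
    return vrs


def make_genome(spec: PlantSpec) -> tuple[AnnotatedSequence, pd.DataFrame]:
    """Build the synthetic contig and its truth table.

    The truth table uses 0-based half-open coordinates in memory (use
    :func:`write_truth_table` for the 1-based-inclusive on-disk form) and
    marks, per planted repeat, whether the default scan (wildcard A) and the
    inverted sweep (wildcard T) should report it.
    """
    rng = np.random.default_rng(spec.seed)
    ctg = _Contig(spec, rng)
    group = spec.arrangement_group
    truth: list[dict] = []
    features: list[Feature] = []

    element_strand = "-" if group == 4 else "+"  # relative to the RT axis

    # --- element pieces -----------------------------------------------------
    protein, prot_meta = make_rt_protein(spec.rt_motif_profile, rng)
    rt_nt = _reverse_translate(rng, protein)

    tr_seq: Optional[str] = None
    vr_draws = []
    if spec.include_element and group != 3:
        tr_seq = _make_tr(rng, spec.tr_length, spec.n_adenines_tr, spec.gc_fraction)
        vr_draws = _build_vrs(tr_seq, rng, spec)

    placements = _default_placements(spec)
    zones: dict[str, list[int]] = {"U": [], "M": [], "D": []}
    if spec.include_element:
        for idx, code in enumerate(placements):
            if code not in zones:
                raise InputError(f"unsupported VR placement code {code!r}")
            if group in (3, 4) and code != "D":
                raise InputError(f"group {group} fixtures support only 'D' placements")
            zones[code].append(idx)

    tr_iv: Optional[tuple[int, int]] = None
    vr_ivs: dict[int, tuple[int, int]] = {}
    target_ivs: dict[int, Optional[tuple[int, int]]] = {}

    def emit_vr(idx: int) -> None:
        vr, offs, targets = vr_draws[idx]
        core = _vr_context(idx, vr)
        if idx in spec.vr_intergenic:
            pad_l = _rand_bases(rng, 30, spec.gc_fraction)
            pad_r = _rand_bases(rng, 30, spec.gc_fraction)
            block = pad_l + core + pad_r
            off = len(pad_l) + 6
            s, e = ctg.place(block, element_strand)
            vr_ivs[idx] = ctg.map_sub(s, e, element_strand, off, off + len(vr))
            target_ivs[idx] = None
        else:
            left = _rand_codons(rng, int(rng.integers(20, 40)))
            right = _rand_codons(rng, int(rng.integers(20, 40)))
            block = "ATG" + left + core + right + "TAA"
            off = 3 + len(left) + 6
            s, e = ctg.place(block, element_strand)
            vr_ivs[idx] = ctg.map_sub(s, e, element_strand, off, off + len(vr))
            target_ivs[idx] = (s, e)

    def emit_tr() -> None:
        nonlocal tr_iv
        s, e = ctg.place(_pad(TR_GUARD, tr_seq), element_strand)
        tr_iv = ctg.map_sub(s, e, element_strand, 2, 2 + len(tr_seq))

    rt_iv: Optional[tuple[int, int]] = None

    def emit_rt() -> None:
        nonlocal rt_iv
        s, e = ctg.place(rt_nt, "+")
        rt_iv = (s, e)

    # --- axis layout ---------------------------------------------------------
    if not spec.include_element:
        emit_rt()
    elif group == 1:
        for i in zones["U"]:
            emit_vr(i)
        emit_tr()
        for i in zones["M"]:
            emit_vr(i)
        emit_rt()
        for i in zones["D"]:
            emit_vr(i)
    elif group == 2:
        for i in zones["U"]:
            emit_vr(i)
        emit_rt()
        for i in zones["M"]:
            emit_vr(i)
        emit_tr()
        for i in zones["D"]:
            emit_vr(i)
    elif group == 3:
        emit_rt()
        # TR = the last `overlap` nt of the RT CDS plus a constructed extension
        ov = spec.group3_overlap
        if ov >= spec.tr_length:
            raise InputError("group3_overlap must be smaller than tr_length")
        tail = "".join(ctg.chars[rt_iv[1] - ov : rt_iv[1]])
        rest_len = spec.tr_length - ov
        need_a = spec.n_adenines_tr - tail.count("A")
        if not 0 <= need_a <= rest_len:
            raise SizingError(
                "group-3 adenine budget infeasible: the RT tail contributes "
                f"{tail.count('A')} adenines, {spec.n_adenines_tr} requested"
            )
        rest = _make_tr(rng, rest_len, need_a, spec.gc_fraction)
        ctg.chars[rt_iv[1] : rt_iv[1] + rest_len] = list(rest)
        tr_seq = tail + rest
        tr_iv = (rt_iv[1] - ov, rt_iv[1] + rest_len)
        # guard bases: two overwrite the RT CDS interior (the TR starts
        # inside the CDS, so there is no intergenic space for them)
        ctg.chars[tr_iv[0] - 2 : tr_iv[0]] = list(TR_GUARD[0])
        ctg.chars[tr_iv[1] : tr_iv[1] + 2] = list(TR_GUARD[1])
        ctg.cursor = tr_iv[1] + 2 + ctg._gap()
        vr_draws = _build_vrs(tr_seq, rng, spec)
        for i in range(spec.n_vr):
            emit_vr(i)
    elif group == 4:
        emit_rt()
        emit_tr()
        for i in range(spec.n_vr):
            emit_vr(i)

    # --- decoys --------------------------------------------------------------
    decoy_rows = []
    for kind in spec.decoys:
        if kind == "exact_duplicate":
            u = _rand_bases(rng, 60, spec.gc_fraction)
            gap_seq = _rand_bases(rng, int(rng.integers(60, 120)), spec.gc_fraction)
            block = _pad(TR_GUARD, u) + gap_seq + _pad(VR_GUARD, u)
            s, e = ctg.place(block)
            a0 = s + 2
            b0 = a0 + 60 + 2 + len(gap_seq) + 2
            decoy_rows.append((kind, (a0, a0 + 60), (b0, b0 + 60), 60, None, 0))
        elif kind == "low_substitution":
            # substitution targets are all T, so no C/G wildcard channel can
            # ever see 7 substitutions even with guard-column leakage
            t = _make_tr(rng, 60, 12, spec.gc_fraction)
            v, offs, _ = _mutate_tr(t, rng, spec.low_substitution_count, {"T": 1.0})
            gap_seq = _rand_bases(rng, int(rng.integers(60, 120)), spec.gc_fraction)
            block = _pad(TR_GUARD, t) + gap_seq + _pad(VR_GUARD, v)
            s, e = ctg.place(block)
            a0 = s + 2
            b0 = a0 + 60 + 2 + len(gap_seq) + 2
            decoy_rows.append((kind, (a0, a0 + 60), (b0, b0 + 60), 12, offs,
                               spec.low_substitution_count))
        elif kind == "non_wildcard_mismatch":
            n = 80
            m = spec.non_wildcard_mismatches
            t = list(_rand_bases(rng, n, spec.gc_fraction))
            step = n // (m + 1)
            if step >= 45:
                raise InputError("non-wildcard mismatches too sparse to stay inert")
            pos = [step * (i + 1) for i in range(m)]
            v = list(t)
            for j, p in enumerate(pos):
                # alternate C and G so that neither the C nor the G wildcard
                # channel sees all mismatches as wildcard columns
                t[p] = "C" if j % 2 == 0 else "G"
                v[p] = "G" if t[p] == "C" else "C"
            gap_seq = _rand_bases(rng, int(rng.integers(60, 120)), spec.gc_fraction)
            block = _pad(TR_GUARD, "".join(t)) + gap_seq + _pad(VR_GUARD, "".join(v))
            s, e = ctg.place(block)
            a0 = s + 2
            b0 = a0 + n + 2 + len(gap_seq) + 2
            decoy_rows.append((kind, (a0, a0 + n), (b0, b0 + n),
                               "".join(t).count("A"), pos, 0))
        elif kind == "homopolymer":
            base = str(rng.choice(list("ACGT")))
            s, e = ctg.place(base * spec.homopolymer_length)
            decoy_rows.append((kind, (s, e), None, None, None, 0))

    # --- features + truth ----------------------------------------------------
    contig_seq = ctg.sequence()
    rt_prot_final = str(Seq(contig_seq[rt_iv[0] : rt_iv[1]]).translate()).rstrip("*")
    features.append(
        Feature(
            "CDS",
            rt_iv[0],
            rt_iv[1],
            "+",
            {
                "locus_tag": "rt1",
                "product": "reverse transcriptase",
                "translation": rt_prot_final,
            },
        )
    )
    truth.append(
        {
            "name": "RT", "kind": "RT", "start": rt_iv[0], "end": rt_iv[1],
            "strand": "+", "length": rt_iv[1] - rt_iv[0], "n_adenines": "",
            "n_substitutions": "", "substitution_offsets": "",
            "detectable_default": 0, "detectable_inverted": 0, "seed": spec.seed,
        }
    )

    if spec.include_element:
        lo, hi = spec.substitution_range
        detectable = (
            spec.n_adenines_tr >= 10
            and all(len(v[1]) >= 7 for v in vr_draws)
        )
        det_def = int(detectable and group != 4)
        det_inv = int(detectable and group == 4)
        features.append(
            Feature(
                "misc_feature", tr_iv[0], tr_iv[1], element_strand,
                {"label": "TR_planted"},
            )
        )
        truth.append(
            {
                "name": "TR", "kind": "TR", "start": tr_iv[0], "end": tr_iv[1],
                "strand": element_strand, "length": spec.tr_length,
                "n_adenines": spec.n_adenines_tr, "n_substitutions": "",
                "substitution_offsets": "", "detectable_default": det_def,
                "detectable_inverted": det_inv, "seed": spec.seed,
            }
        )
        for idx in range(spec.n_vr):
            vr, offs, _ = vr_draws[idx]
            iv = vr_ivs[idx]
            features.append(
                Feature(
                    "misc_feature", iv[0], iv[1], element_strand,
                    {"label": f"VR{idx + 1}_planted"},
                )
            )
            this_det = int(spec.n_adenines_tr >= 10 and len(offs) >= 7)
            truth.append(
                {
                    "name": f"VR{idx + 1}", "kind": "VR", "start": iv[0],
                    "end": iv[1], "strand": element_strand,
                    "length": spec.tr_length,
                    "n_adenines": spec.n_adenines_tr,
                    "n_substitutions": len(offs),
                    "substitution_offsets": ",".join(map(str, offs)),
                    "detectable_default": this_det if group != 4 else 0,
                    "detectable_inverted": this_det if group == 4 else 0,
                    "seed": spec.seed,
                }
            )
            tgt = target_ivs[idx]
            if tgt is not None:
                features.append(
                    Feature(
                        "CDS", tgt[0], tgt[1], element_strand,
                        {
                            "locus_tag": f"target_{idx + 1}",
                            "product": "hypothetical diversified protein",
                        },
                    )
                )
                truth.append(
                    {
                        "name": f"target_{idx + 1}", "kind": "target_CDS",
                        "start": tgt[0], "end": tgt[1], "strand": element_strand,
                        "length": tgt[1] - tgt[0], "n_adenines": "",
                        "n_substitutions": "", "substitution_offsets": "",
                        "detectable_default": 0, "detectable_inverted": 0,
                        "seed": spec.seed,
                    }
                )

    for i, (kind, iv_a, iv_b, n_a, offs, n_sub) in enumerate(decoy_rows):
        for suffix, iv in (("a", iv_a), ("b", iv_b)):
            if iv is None:
                continue
            truth.append(
                {
                    "name": f"decoy{i + 1}_{suffix}", "kind": f"decoy_{kind}",
                    "start": iv[0], "end": iv[1], "strand": "+",
                    "length": iv[1] - iv[0],
                    "n_adenines": n_a if n_a is not None else "",
                    "n_substitutions": n_sub,
                    "substitution_offsets": ",".join(map(str, offs)) if offs else "",
                    "detectable_default": 0, "detectable_inverted": 0,
                    "seed": spec.seed,
                }
            )

    # flip the whole contig when the RT is requested on the minus strand
    if spec.rt_strand == "-":
        Lc = spec.background_length
        contig_seq = revcomp(contig_seq)
        features = [
            Feature(
                f.kind, Lc - f.end, Lc - f.start,
                "-" if f.strand == "+" else "+", f.qualifiers,
            )
            for f in features
        ]
        for row in truth:
            row["start"], row["end"] = Lc - row["end"], Lc - row["start"]
            row["strand"] = "-" if row["strand"] == "+" else "+"

    features.sort(key=lambda f: f.start)
    seq = AnnotatedSequence(
        id=f"synctg{spec.seed}",
        residues=contig_seq,
        features=features,
        source={
            "organism": "synthetic bacterium",
            "description": f"synthetic DGR fixture (seed {spec.seed})",
        },
    )
    df = pd.DataFrame(truth, columns=_TRUTH_COLUMNS)
    return seq, df


def fixture_anchor(seq: AnnotatedSequence) -> RTAnchor:
    """The RT anchor of a generated fixture."""
    from .io_genbank import find_rt_anchors

    anchors = find_rt_anchors(seq)
    if not anchors:
        raise InputError("fixture carries no RT CDS")
    return anchors[0]


def write_truth_table(df: pd.DataFrame, path) -> None:
    """Write the truth table with 1-based inclusive coordinates."""
    out = df.copy()
    out["start"] = out["start"] + 1
    out["substitution_offsets"] = out["substitution_offsets"].map(
        lambda s: ",".join(str(int(x) + 1) for x in str(s).split(",")) if s else ""
    )
    out.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    """Read a truth table back into the in-memory (0-based) convention."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["start"] = df["start"] - 1
    df["substitution_offsets"] = df["substitution_offsets"].map(
        lambda s: ",".join(str(int(x) - 1) for x in str(s).split(",")) if s else ""
    )
    return df


def spec_to_dict(spec: PlantSpec) -> dict:
    """The spec as plain YAML-friendly types (tuples become lists)."""
    d = asdict(spec)
    d["substitution_bias"] = dict(spec.substitution_bias)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_fixture(spec: PlantSpec, outdir) -> dict:
    """Write contig.gbk, truth.tsv, anchors.tsv and spec.yaml into ``outdir``."""
    import os

    import yaml

    from .io_genbank import write_genbank

    os.makedirs(outdir, exist_ok=True)
    seq, truth = make_genome(spec)
    paths = {
        "genbank": os.path.join(outdir, "contig.gbk"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "anchors": os.path.join(outdir, "anchors.tsv"),
        "spec": os.path.join(outdir, "spec.yaml"),
    }
    write_genbank(seq, paths["genbank"])
    write_truth_table(truth, paths["truth"])
    anchor = fixture_anchor(seq)
    with open(paths["anchors"], "w") as out:
        out.write("sequence_id\tstart\tend\tstrand\tlabel\n")
        out.write(
            f"{anchor.sequence_id}\t{anchor.cds_interval[0] + 1}\t"
            f"{anchor.cds_interval[1]}\t{anchor.strand}\t{anchor.label}\n"
        )
    with open(paths["spec"], "w") as out:
        yaml.safe_dump(spec_to_dict(spec), out, sort_keys=False)
    return paths


def make_repeat_sequence(
    seed: Union[int, np.random.Generator],
    length: int = 2000,
    gc: float = 0.5,
    tr_length: int = 50,
    n_adenines: int = 12,
    n_substitutions: int = 8,
    plant: bool = True,
) -> tuple[str, Optional[dict]]:
    """A bare random sequence, optionally with one flank-guarded TR/VR pair.

    A lighter companion to :func:`make_genome` for scanner-level tests: no RT,
    no ORFs, just the repeat pair in background.  Returns (residues, truth)
    where truth carries the planted intervals and substitution offsets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues = list(_rand_bases(rng, length, gc))
    if not plant:
        return "".join(residues), None
    tr = _make_tr(rng, tr_length, n_adenines, gc)
    vr, offs, _ = _mutate_tr(tr, rng, n_substitutions, {"C": 1, "G": 3, "T": 2})
    span = tr_length + 2
    p1 = int(rng.integers(50, length // 2 - span - 60))
    p2 = int(rng.integers(length // 2 + 60, length - span - 50))
    residues[p1 : p1 + span] = list("C" + tr + "C")
    residues[p2 : p2 + span] = list("G" + vr + "G")
    truth = {
        "tr_interval": (p1 + 1, p1 + 1 + tr_length),
        "vr_interval": (p2 + 1, p2 + 1 + tr_length),
        "n_adenines": n_adenines,
        "substitution_offsets": offs,
    }
    return "".join(residues), truth
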