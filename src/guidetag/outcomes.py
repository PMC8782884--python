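"""Per-UMI editing-outcome classification at a locus viewpoint.

Each retained UMI contributes a single exemplar read which is assigned to
exactly one editing category: wild type, precise edit, small indel or
substitution (< 50 bp), large deletion/insertion (>= 50 bp), donor
insertion (forward/reverse), vector insertion, translocation candidate, or
unexplained. Split-read alignment against genome + donor + vector supplies
the junction evidence; junctions are annotated with untemplated inserted
bases and flanking microhomology.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import edlib

from .align import KmerIndex, SplitResult, parse_edlib_cigar, split_align
from .seqio import GenomicInterval

#: Reserved reference names for non-genomic sequences in the k-mer index.
DONOR_REF = "__donor__"
VECTOR_REF = "__vector__"

#: Indel span (bp) separating "small" from "large" events. The boundary
#: value 50 itself is assigned to the large class so the mapping is total.
SMALL_INDEL_MAX = 50


class EditClass(str, Enum):
    wild_type = "wild_type"
    precise_edit = "precise_edit"
    small_indel_sub = "small_indel_sub"
    large_del_ins = "large_del_ins"
    donor_forward = "donor_forward"
    donor_reverse = "donor_reverse"
    vector_insertion = "vector_insertion"
    translocation_candidate = "translocation_candidate"
    unexplained = "unexplained"


#: Classes counted as edited (non-wild-type) in rate denominators.
EDITED_CLASSES = frozenset(EditClass) - {EditClass.wild_type}


def blunt_cut(start: int, end: int, strand: str) -> int:
    """Predicted blunt SpyCas9 cut: 3 bp 5' of the PAM, protospacer strand.

    For a protospacer on [start, end) with the PAM 3' of it, the cut falls
    between positions end-4|end-3 on the + strand (coordinate end-3 as the
    first base of the PAM-proximal fragment) and symmetrically for '-'.
    """
    return end - 3 if strand == "+" else start + 3


@dataclass
class LocusSpec:
    """A target locus: reference window around the cut plus the cut site."""

    contig: str
    window: GenomicInterval
    cut_site: int

    def __post_init__(self) -> None:
        if not (self.window.start <= self.cut_site <= self.window.end):
            raise ValueError("cut site must lie within the locus window")


@dataclass
class JunctionAnnotation:
    """Breakpoints of a junction with inserted bases and microhomology."""

    left_break: int | None = None
    right_break: int | None = None
    inserted_bases: str = ""
    deletion_length: int = 0
    microhomology_length: int = 0
    microhomology_seq: str = ""
    precise: bool = False


@dataclass
class Classification:
    edit_class: EditClass
    junction: JunctionAnnotation | None = None
    split: SplitResult | None = None
    partner: tuple[str, int, str] | None = None  # distal (contig, pos, strand)


def _cigar_events_in_window(cigar, aln_ref_start: int, lo: int, hi: int):
    """(del_bp, ins_bp, sub_bp) from cigar ops overlapping [lo, hi).

    Substitutions are invisible in an M-merged cigar, so ``sub_bp`` here
    counts only X ops when present; callers needing substitution detail
    compare sequences directly.
    """
    ref = aln_ref_start
    del_bp = ins_bp = 0
    for op, n in cigar:
        if op == "M":
            ref += n
        elif op == "D":
            if ref < hi and ref + n > lo:
                del_bp += n
            ref += n
        elif op == "I":
            if lo <= ref <= hi:
                ins_bp += n
    return del_bp, ins_bp


def classify_exemplar(
    payload: str,
    index: KmerIndex,
    locus: LocusSpec,
    cut_window: int = 10,
    sub_allowance: int = 1,
    max_cis_deletion: int = 50_000,
) -> Classification:
    """Assign one exemplar read to an editing category.

    Decision order: a second split segment on the donor reference gives
    donor_forward/donor_reverse (orientation relative to the genomic arm);
    on the vector, vector_insertion; on a distal genomic locus (different
    contig, opposite strand, or beyond ``max_cis_deletion``),
    translocation_candidate. Same-contig same-strand splits are deletions,
    large or small by the 50 bp boundary. Single-segment reads are aligned
    to the locus window and classified by indel content in the cut window
    (substitutions count only beyond a ``sub_allowance`` meant to absorb
    sequencing error); reads that cannot be explained at all are
    ``unexplained``.
    """
    split = split_align(payload, index)
    if split.is_split:
        return _classify_split(payload, index, locus, split, max_cis_deletion)
    if not split.segments or split.unexplained_clip:
        # fall back to a direct window alignment before giving up
        cls = _classify_single(payload, index, locus, cut_window, sub_allowance)
        if cls is not None:
            return cls
        return Classification(EditClass.unexplained, split=split)
    seg = split.segments[0]
    if seg.ref != locus.contig:
        return Classification(EditClass.unexplained, split=split)
    cls = _classify_single(payload, index, locus, cut_window, sub_allowance)
    return cls if cls is not None else Classification(EditClass.unexplained,
                                                     split=split)


def _classify_split(payload, index, locus, split, max_cis_deletion):
    seg1, seg2 = split.segments[0], split.segments[1]
    junction = detect_breakpoints(split)
    if seg2.ref == DONOR_REF:
        forward = seg2.strand == seg1.strand
        cls = EditClass.donor_forward if forward else EditClass.donor_reverse
        junction.precise = precise_junction_check(
            split, donor_length=len(index.refs[DONOR_REF]),
            cut_site=locus.cut_site)
        _annotate_microhomology(junction, index, seg1, seg2)
        return Classification(cls, junction=junction, split=split)
    if seg2.ref == VECTOR_REF:
        return Classification(EditClass.vector_insertion, junction=junction,
                              split=split)
    # genomic partner
    same_cis = (seg2.ref == seg1.ref and seg2.strand == seg1.strand
                and 0 <= seg2.ref_start - seg1.ref_end <= max_cis_deletion)
    if same_cis:
        _annotate_microhomology(junction, index, seg1, seg2)
        span = junction.deletion_length + len(junction.inserted_bases)
        cls = (EditClass.large_del_ins if span >= SMALL_INDEL_MAX
               else EditClass.small_indel_sub)
        return Classification(cls, junction=junction, split=split)
    partner_pos = seg2.ref_start if seg2.strand == "+" else seg2.ref_end - 1
    return Classification(
        EditClass.translocation_candidate, junction=junction, split=split,
        partner=(seg2.ref, partner_pos, seg2.strand))


def _classify_single(payload, index, locus, cut_window, sub_allowance):
    ref = index.refs[locus.contig]
    lo, hi = locus.window.start, locus.window.end
    res = edlib.align(payload, ref[lo:hi], mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    max_edit = max(SMALL_INDEL_MAX + 5, int(0.2 * len(payload)))
    if res["editDistance"] > max_edit:
        return None
    start = lo + res["locations"][0][0]
    cigar = parse_edlib_cigar(res["cigar"])
    w_lo, w_hi = locus.cut_site - cut_window, locus.cut_site + cut_window
    del_bp, ins_bp = _cigar_events_in_window(cigar, start, w_lo, w_hi)
    indel_span = del_bp + ins_bp
    if indel_span >= SMALL_INDEL_MAX:
        return Classification(EditClass.large_del_ins,
                              junction=JunctionAnnotation(
                                  deletion_length=del_bp,
                                  inserted_bases="?" * ins_bp))
    if indel_span > 0:
        return Classification(EditClass.small_indel_sub,
                              junction=JunctionAnnotation(
                                  deletion_length=del_bp,
                                  inserted_bases="?" * ins_bp))
    subs = _substitutions_in_window(payload, ref, start, cigar, w_lo, w_hi)
    if subs > sub_allowance:
        return Classification(EditClass.small_indel_sub)
    return Classification(EditClass.wild_type)


def _substitutions_in_window(payload, ref, ref_start, cigar, lo, hi) -> int:
    qpos, rpos = 0, ref_start
    subs = 0
    for op, n in cigar:
        if op == "M":
            for i in range(n):
                if lo <= rpos + i < hi and payload[qpos + i] != ref[rpos + i]:
                    subs += 1
            qpos += n
            rpos += n
        elif op == "I":
            qpos += n
        elif op == "D":
            rpos += n
    return subs


def detect_breakpoints(split: SplitResult) -> JunctionAnnotation:
    """Reference breakpoints implied by an ordered pair of split segments.

    For same-reference same-strand segments the deletion length is the gap
    between them; overlapping segments (microhomology consumed twice) are
    modelled as non-overlapping, giving deletion length 0.
    """
    if not split.is_split:
        return JunctionAnnotation()
    seg1, seg2 = split.segments[0], split.segments[1]
    left = seg1.ref_end if seg1.strand == "+" else seg1.ref_start
    right = seg2.ref_start if seg2.strand == "+" else seg2.ref_end
    deletion = 0
    if seg1.ref == seg2.ref and seg1.strand == seg2.strand == "+":
        deletion = max(0, seg2.ref_start - seg1.ref_end)
    elif seg1.ref == seg2.ref and seg1.strand == seg2.strand == "-":
        deletion = max(0, seg1.ref_start - seg2.ref_end)
    return JunctionAnnotation(
        left_break=left, right_break=right,
        inserted_bases=split.inserted_bases,
        deletion_length=deletion,
    )


def microhomology(reference: str, left_break: int,
                  right_break: int) -> tuple[int, str, str]:
    """Longest identical flank shared by the two sides of a junction.

    Returns (length, sequence, side) where side is "upstream" when
    ref[left-k:left) == ref[right-k:right) and "downstream" when
    ref[left:left+k) == ref[right:right+k); the longer of the two wins
    (ties -> upstream).
    """
    if not (0 <= left_break < right_break <= len(reference)):
        raise ValueError("breaks must satisfy 0 <= left < right <= len(ref)")
    up = 0
    while (up < left_break
           and reference[left_break - up - 1] == reference[right_break - up - 1]):
        up += 1
    down = 0
    while (right_break + down < len(reference)
           and reference[left_break + down] == reference[right_break + down]):
        down += 1
    if up >= down:
        return up, reference[left_break - up:left_break], "upstream"
    return down, reference[right_break:right_break + down], "downstream"


def _annotate_microhomology(junction, index, seg1, seg2) -> None:
    if (seg1.ref != seg2.ref or seg1.strand != seg2.strand
            or junction.left_break is None):
        return
    ref = index.refs[seg1.ref]
    if seg1.strand == "+":
        left, right = junction.left_break, junction.right_break
    else:
        left, right = junction.right_break, junction.left_break
    if left is None or right is None or left >= right:
        return
    k, seq, _ = microhomology(ref, left, right)
    junction.microhomology_length = k
    junction.microhomology_seq = seq


def precise_junction_check(split: SplitResult, donor_length: int,
                           cut_site: int) -> bool:
    """Is a donor junction a perfect blunt ligation at the predicted cut?

    Precise means the genomic arm ends exactly at the blunt cut site, the
    donor segment starts at its first base (last base when inserted in
    reverse orientation), and no untemplated bases sit at the junction.

    Microhomology between the arm end and the donor terminus makes the
    junction placement ambiguous; a junction shifted by d bases into both
    references simultaneously (which the split aligner produces only when
    the bases genuinely match) still counts as precise.
    """
    if not split.is_split or split.segments[1].ref != DONOR_REF:
        return False
    seg1, seg2 = split.segments[0], split.segments[1]
    if split.inserted_bases:
        return False
    d_arm = (seg1.ref_end - cut_site if seg1.strand == "+"
             else cut_site - seg1.ref_start)
    if seg2.strand == seg1.strand:       # forward insertion
        d_donor = seg2.ref_start
    else:                                # reverse insertion
        d_donor = donor_length - seg2.ref_end
    return d_arm >= 0 and d_arm == d_donor


@dataclass
class OutcomeTable:
    """UMI counts and fractions per editing category at one viewpoint."""

    sample: str
    viewpoint: str
    locus: str
    counts: dict[EditClass, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[EditClass, float] | None:
        """Per-class fraction of classified UMIs; None for an empty table."""
        if self.total == 0:
            return None
        return {c: self.counts.get(c, 0) / self.total for c in EditClass}

    @property
    def edited_total(self) -> int:
        return sum(n for c, n in self.counts.items() if c in EDITED_CLASSES)


def tabulate_outcomes(classifications: Iterable[Classification | EditClass],
                      sample: str = "", viewpoint: str = "",
                      locus: str = "") -> OutcomeTable:
    """Count classified exemplars into an :class:`OutcomeTable`."""
    counts: Counter = Counter()
    for c in classifications:
        cls = c.edit_class if isinstance(c, Classification) else EditClass(c)
        counts[cls] += 1
    return OutcomeTable(sample=sample, viewpoint=viewpoint, locus=locus,
                        counts=dict(counts))


@dataclass
class AmpliconIndelResult:
    indel_pct: float
    n_aligned: int
    n_edited: int
    low_coverage: bool


def quantify_amplicon_indels(
    reads: Sequence[str],
    amplicon_ref: str,
    cut_site: int,
    window: int = 10,
    min_reads: int = 100,
) -> AmpliconIndelResult:
    """Fraction of amplicon reads carrying an indel near the cut site.

    A read counts as edited when its alignment to the amplicon contains at
    least one inserted or deleted base overlapping cut_site +/- ``window``;
    substitutions alone never count. Results from fewer than ``min_reads``
    aligned reads are flagged low-coverage.
    """
    lo, hi = cut_site - window, cut_site + window
    n_aligned = n_edited = 0
    for read in reads:
        res = edlib.align(read, amplicon_ref, mode="HW", task="path")
        if res["editDistance"] < 0 or res["editDistance"] > 0.3 * len(read):
            continue
        n_aligned += 1
        cigar = parse_edlib_cigar(res["cigar"])
        start = res["locations"][0][0]
        del_bp, ins_bp = _cigar_events_in_window(cigar, start, lo, hi)
        if del_bp + ins_bp > 0:
            n_edited += 1
    pct = 100.0 * n_edited / n_aligned if n_aligned else 0.0
    return AmpliconIndelResult(indel_pct=pct, n_aligned=n_aligned,
                               n_edited=n_edited,
                               low_coverage=n_aligned < min_reads)
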