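"""Demultiplexing, UMI extraction, pair merging, and tag/primer trimming.

A tagmented library read pair carries, on the adapter side, a UMI and a
sample barcode at fixed offsets, and on the viewpoint side either a
locus-specific primer (UDiTaS locus viewpoints) or residual dsODN tag
sequence (insert viewpoints). Reads from insert viewpoints that lack the
expected tag at the read start are mispriming products and are discarded
before any integration-site calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .seqio import SequenceRecord, revcomp

LOCUS_VIEWPOINTS = ("Locus_F", "Locus_R")
INSERT_VIEWPOINTS = ("Insert_F", "Insert_R")
VIEWPOINTS = LOCUS_VIEWPOINTS + INSERT_VIEWPOINTS


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class LibraryLayout:
    """Where the UMI, barcode, primers and tag live within a read pair.

    ``umi_offset``/``barcode_offset`` index into the adapter-side read.
    ``viewpoint_primers`` maps each locus viewpoint to its gene-specific
    primer; ``tag_prefixes`` maps each insert viewpoint to the residual tag
    sequence expected at the start of the trimmed viewpoint-side read.
    """

    viewpoint_primers: dict[str, str]
    tag_prefixes: dict[str, str]
    umi_length: int = 8
    umi_offset: int = 0
    barcode_length: int = 8
    barcode_offset: int = 8
    min_payload: int = 20
    tag_tolerance: float = 0.9  # minimum prefix identity, no indels

    def __post_init__(self) -> None:
        u = (self.umi_offset, self.umi_offset + self.umi_length)
        b = (self.barcode_offset, self.barcode_offset + self.barcode_length)
        if max(u[0], b[0]) < min(u[1], b[1]):
            raise ValueError("UMI and barcode segments overlap")
        for vp in self.viewpoint_primers:
            if vp not in LOCUS_VIEWPOINTS:
                raise ValueError(f"unknown locus viewpoint {vp!r}")
        for vp in self.tag_prefixes:
            if vp not in INSERT_VIEWPOINTS:
                raise ValueError(f"unknown insert viewpoint {vp!r}")

    @property
    def adapter_segment_end(self) -> int:
        return max(self.umi_offset + self.umi_length,
                   self.barcode_offset + self.barcode_length)

    def prefixes(self) -> dict[str, str]:
        """Viewpoint -> expected viewpoint-side read prefix."""
        return {**self.viewpoint_primers, **self.tag_prefixes}


@dataclass
class TaggedRead:
    """A fully demultiplexed read: sample, UMI, viewpoint and payload."""

    sample: str
    umi: str
    viewpoint: str
    payload: str
    provenance: str

    def __post_init__(self) -> None:
        if "N" in self.umi:
            raise ValueError("UMI must not contain N")
        if not self.payload:
            raise ValueError("payload must be non-empty")
        if self.viewpoint not in VIEWPOINTS:
            raise ValueError(f"unknown viewpoint {self.viewpoint!r}")


@dataclass
class PreprocessStats:
    """Read accounting; assigned + ambiguous + unassigned + rejected = total."""

    total: int = 0
    assigned: int = 0
    ambiguous_barcode: int = 0
    unassigned_barcode: int = 0
    umi_with_n: int = 0
    too_short: int = 0
    no_viewpoint: int = 0
    mispriming: int = 0
    short_payload: int = 0
    passed: int = 0

    @property
    def rejected(self) -> int:
        return (self.umi_with_n + self.too_short + self.no_viewpoint
                + self.mispriming + self.short_payload)


def check_barcode_separation(barcodes: dict[str, str],
                             max_mismatch: int = 1) -> None:
    """Warn when two sample barcodes are close enough to collide."""
    names = sorted(barcodes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if hamming(barcodes[a], barcodes[b]) <= 2 * max_mismatch:
                warnings.warn(
                    f"barcodes for {a!r} and {b!r} are within 2*max_mismatch; "
                    "ambiguous assignments will be discarded", stacklevel=2)


def demultiplex(observed: str, barcodes: dict[str, str],
                max_mismatch: int = 1) -> str | None:
    """Assign an observed barcode to the unique sample within distance.

    Returns the sample name, or None when no barcode (or more than one)
    lies within ``max_mismatch``. Ambiguity is resolved by discarding, never
    by nearest-neighbour assignment, so UMI counts stay uncontaminated.
    """
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have equal length")
    (blen,) = lengths
    if len(observed) < blen:
        return None
    observed = observed[:blen]
    hits = [name for name, bc in barcodes.items()
            if hamming(observed, bc) <= max_mismatch]
    return hits[0] if len(hits) == 1 else None


def extract_umi(read: SequenceRecord | str, layout: LibraryLayout) -> str | None:
    """UMI substring of the adapter-side read; None if too short or has N."""
    seq = read if isinstance(read, str) else read.sequence
    end = layout.umi_offset + layout.umi_length
    if len(seq) < end:
        return None
    umi = seq[layout.umi_offset:end]
    return None if "N" in umi else umi


def extract_barcode(read: SequenceRecord | str, layout: LibraryLayout) -> str | None:
    seq = read if isinstance(read, str) else read.sequence
    end = layout.barcode_offset + layout.barcode_length
    return seq[layout.barcode_offset:end] if len(seq) >= end else None


def merge_pairs(r1: SequenceRecord, r2: SequenceRecord,
                min_overlap: int = 10,
                max_overlap_mismatch_rate: float = 0.1
                ) -> SequenceRecord | None:
    """Merge an overlapping read pair into one consensus read.

    R2 is interpreted on the opposite strand. The 3' end of R1 is slid over
    the (reverse-complemented) 5' end of R2; the longest overlap of at least
    ``min_overlap`` bases whose mismatch rate stays within the threshold
    wins. In the overlap the base with the higher quality score is kept.
    Returns None when no acceptable overlap exists (pair stays unmerged).
    """
    s1, s2 = r1.sequence, revcomp(r2.sequence)
    q1 = r1.quality or "I" * len(s1)
    q2 = (r2.quality or "I" * len(r2.sequence))[::-1]
    best: tuple[int, int] | None = None  # (overlap, mismatches)
    for o in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        mism = hamming(s1[len(s1) - o:], s2[:o])
        if mism <= max_overlap_mismatch_rate * o:
            best = (o, mism)
            break
    if best is None:
        return None
    o = best[0]
    head = s1[:len(s1) - o]
    tail = s2[o:]
    consensus = []
    cons_q = []
    for i in range(o):
        a, b = s1[len(s1) - o + i], s2[i]
        qa, qb = q1[len(s1) - o + i], q2[i]
        if a == b or qa >= qb:
            consensus.append(a)
            cons_q.append(max(qa, qb) if a == b else qa)
        else:
            consensus.append(b)
            cons_q.append(qb)
    return SequenceRecord(
        id=r1.id, mate="merged",
        sequence=head + "".join(consensus) + tail,
        quality=q1[:len(s1) - o] + "".join(cons_q) + q2[o:],
    )


def assign_viewpoint(seq: str, layout: LibraryLayout) -> str | None:
    """Viewpoint whose expected prefix best matches the read start.

    The prefix (locus primer or residual tag) must match at >=
    ``layout.tag_tolerance`` identity over its full length, ungapped. The
    best-identity viewpoint wins; ties go to the first in canonical order.
    """
    best: tuple[float, str] | None = None
    for vp in VIEWPOINTS:
        prefix = layout.prefixes().get(vp)
        if prefix is None or len(seq) < len(prefix):
            continue
        ident = 1.0 - hamming(seq[:len(prefix)], prefix) / len(prefix)
        if ident >= layout.tag_tolerance and (best is None or ident > best[0]):
            best = (ident, vp)
    return best[1] if best else None


def trim_and_filter(seq: str, layout: LibraryLayout,
                    viewpoint: str) -> str | None:
    """Trim the viewpoint prefix and return the genomic payload.

    For insert viewpoints the residual tag prefix must be present at the
    read start within the identity tolerance; reads lacking it are
    mispriming products and are discarded (None). Locus viewpoints only
    require their primer. Payloads shorter than ``layout.min_payload`` are
    discarded.
    """
    prefix = layout.prefixes().get(viewpoint)
    if prefix is None:
        raise KeyError(f"no prefix configured for viewpoint {viewpoint!r}")
    if len(seq) < len(prefix):
        return None
    ident = 1.0 - hamming(seq[:len(prefix)], prefix) / len(prefix)
    if ident < layout.tag_tolerance:
        return None
    payload = seq[len(prefix):]
    return payload if len(payload) >= layout.min_payload else None


def process_pair(
    r1: SequenceRecord,
    r2: SequenceRecord,
    layout: LibraryLayout,
    barcodes: dict[str, str],
    stats: PreprocessStats,
    max_barcode_mismatch: int = 1,
) -> TaggedRead | None:
    """Full per-pair preprocessing: demultiplex, UMI, viewpoint, trim.

    R1 is the viewpoint-side read; R2 the adapter side carrying UMI and
    barcode. Every outcome increments exactly one stats counter.
    """
    stats.total += 1
    if len(r2.sequence) < layout.adapter_segment_end:
        stats.too_short += 1
        return None
    observed = extract_barcode(r2, layout)
    hits = [name for name, bc in barcodes.items()
            if hamming(observed[:len(bc)], bc) <= max_barcode_mismatch]
    if len(hits) > 1:
        stats.ambiguous_barcode += 1
        return None
    if not hits:
        stats.unassigned_barcode += 1
        return None
    sample = hits[0]
    umi = extract_umi(r2, layout)
    if umi is None:
        stats.umi_with_n += 1
        return None
    viewpoint = assign_viewpoint(r1.sequence, layout)
    if viewpoint is None:
        vp_guess = _nearest_viewpoint(r1.sequence, layout)
        if vp_guess in INSERT_VIEWPOINTS:
            stats.mispriming += 1
        else:
            stats.no_viewpoint += 1
        return None
    payload = trim_and_filter(r1.sequence, layout, viewpoint)
    if payload is None:
        stats.short_payload += 1
        return None
    stats.assigned += 1
    stats.passed += 1
    return TaggedRead(sample=sample, umi=umi, viewpoint=viewpoint,
                      payload=payload, provenance=r1.id)


def _nearest_viewpoint(seq: str, layout: LibraryLayout) -> str | None:
    """Best viewpoint prefix ignoring the identity tolerance (for stats)."""
    best: tuple[float, str] | None = None
    for vp, prefix in layout.prefixes().items():
        if len(seq) < len(prefix):
            continue
        ident = 1.0 - hamming(seq[:len(prefix)], prefix) / len(prefix)
        if best is None or ident > best[0]:
            best = (ident, vp)
    return best[1] if best else None
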