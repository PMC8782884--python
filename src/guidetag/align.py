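"""Built-in seed-and-extend read aligner and split-read (junction) aligner.

The contract mirrors what an external end-to-end aligner provides (SAM can
be ingested instead via :func:`guidetag.seqio.ingest_alignments`); the
built-in engine exists so toy genomes and the test suite need no external
binary. Seeding is exact k-mer lookup; extension/verification is edit-
distance alignment (edlib), which is equivalent to unit-cost dynamic
programming over the candidate window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import edlib

from .seqio import GenomeRef, GenomicInterval, revcomp

CigarList = list[tuple[str, int]]


@dataclass
class Alignment:
    """An end-to-end alignment of a read (or read segment) to a reference."""

    read_id: str
    interval: GenomicInterval
    cigar: CigarList
    edit_distance: int
    query_start: int = 0       # offset of the aligned segment within the read
    query_end: int | None = None

    def __post_init__(self) -> None:
        span = sum(n for op, n in self.cigar if op in "MD")
        if span != len(self.interval):
            raise ValueError(
                f"cigar reference span {span} != interval length {len(self.interval)}")

    @property
    def strand(self) -> str:
        return self.interval.strand


def parse_edlib_cigar(cigar: str) -> CigarList:
    """Edlib extended cigar -> [(op, len)] with '='/'X' merged into M."""
    out: CigarList = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            op = "M" if ch in "=X" else ch
            n = int(num)
            num = ""
            if out and out[-1][0] == op:
                out[-1] = (op, out[-1][1] + n)
            else:
                out.append((op, n))
    return out


def cigar_ref_span(cigar: CigarList) -> int:
    return sum(n for op, n in cigar if op in "MD")


class KmerIndex:
    """Exact k-mer index over a set of named reference sequences.

    K-mers occurring more than ``max_hits`` times are dropped from the index
    (repeat masking); seeding then simply skips them.
    """

    def __init__(self, refs: dict[str, str], k: int = 13, max_hits: int = 64):
        self.k = k
        self.refs = refs
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in refs.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                hits = index.get(kmer)
                if hits is None:
                    index[kmer] = [(name, pos)]
                elif len(hits) <= max_hits:
                    hits.append((name, pos))
        self.index = {km: h for km, h in index.items() if len(h) <= max_hits}

    @classmethod
    def from_genome(cls, genome: GenomeRef, k: int = 13, max_hits: int = 64,
                    extra: dict[str, str] | None = None) -> "KmerIndex":
        refs = dict(genome.contigs)
        if extra:
            refs.update(extra)
        return cls(refs, k=k, max_hits=max_hits)

    def seed_hits(self, seq: str, step: int | None = None):
        """Yield (query_offset, ref_name, ref_pos) exact seed matches."""
        step = step or self.k
        k = self.k
        offsets = list(range(0, max(len(seq) - k, 0) + 1, step))
        if offsets and offsets[-1] != len(seq) - k:
            offsets.append(len(seq) - k)
        for off in offsets:
            for name, pos in self.index.get(seq[off:off + k], ()):
                yield off, name, pos


def _align_window(payload: str, ref: str, lo: int, hi: int):
    """Infix-align payload against ref[lo:hi); returns (edit, start, cigar)."""
    window = ref[lo:hi]
    if len(window) < 1:
        return None
    res = edlib.align(payload, window, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], lo + start, lo + end + 1, parse_edlib_cigar(res["cigar"])


def align_read(
    payload: str,
    index: KmerIndex,
    read_id: str = "read",
    max_edit: int | None = None,
    seed_step: int | None = None,
    pad: int = 12,
) -> Alignment | None:
    """Best end-to-end alignment of ``payload`` against the indexed genome.

    Exact seeds anchor candidate diagonals on both strands; each candidate
    window is verified by edit-distance DP. Unaligned (no seed, or best edit
    distance above ``max_edit``, default 15% of the read length) is a normal
    outcome. Ties break to the leftmost coordinate, then the + strand.
    """
    if len(payload) < index.k:
        return None
    if max_edit is None:
        max_edit = max(3, int(0.15 * len(payload)))
    best: tuple | None = None  # (edit, contig, start, strand_rank, cigar, end)
    for strand, seq in (("+", payload), ("-", revcomp(payload))):
        diagonals: set[tuple[str, int]] = set()
        for off, name, pos in index.seed_hits(seq, step=seed_step):
            diagonals.add((name, max(pos - off, 0)))
        # merge nearby diagonals so one DP window covers small indels
        merged: dict[str, list[int]] = {}
        for name, d in sorted(diagonals):
            row = merged.setdefault(name, [])
            if row and d - row[-1] <= pad:
                continue
            row.append(d)
        for name, diags in merged.items():
            ref = index.refs[name]
            for d in diags:
                lo = max(d - pad, 0)
                hi = min(d + len(seq) + pad, len(ref))
                hit = _align_window(seq, ref, lo, hi)
                if hit is None:
                    continue
                edit, start, end, cigar = hit
                key = (edit, name, start, 0 if strand == "+" else 1)
                if best is None or key < best[:4]:
                    best = (edit, name, start, key[3], cigar, end)
    if best is None or best[0] > max_edit:
        return None
    edit, name, start, strand_rank, cigar, end = best
    return Alignment(
        read_id=read_id,
        interval=GenomicInterval(name, start, end, "+" if strand_rank == 0 else "-"),
        cigar=cigar,
        edit_distance=edit,
    )


def five_prime_start(aln: Alignment) -> int:
    """Genomic coordinate of the read's 5' end (strand-aware)."""
    return aln.interval.start if aln.strand == "+" else aln.interval.end - 1


# ---------------------------------------------------------------------------
# Split-read alignment (junction discovery)
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One piece of a split read mapped to a reference."""

    ref: str
    strand: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    edit_distance: int = 0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class SplitResult:
    """Outcome of split alignment: 1-2 segments plus junction information."""

    segments: list[Segment] = field(default_factory=list)
    junction_offset: int | None = None     # read offset where segment 2 begins
    inserted_bases: str = ""               # untemplated bases at the junction
    unexplained_clip: bool = False

    @property
    def is_split(self) -> bool:
        return len(self.segments) >= 2


@dataclass
class _Chain:
    ref: str
    strand: str
    diag: int
    q_lo: int
    q_hi: int
    n_seeds: int = 1


def _chain_seeds(seq: str, index: KmerIndex, strand: str, step: int,
                 diag_tol: int = 8) -> list[_Chain]:
    chains: list[_Chain] = []
    for off, name, pos in index.seed_hits(seq, step=step):
        diag = pos - off
        for ch in chains:
            if ch.ref == name and abs(ch.diag - diag) <= diag_tol \
                    and off - ch.q_hi <= 3 * step:
                ch.q_hi = max(ch.q_hi, off + index.k)
                ch.q_lo = min(ch.q_lo, off)
                ch.n_seeds += 1
                break
        else:
            chains.append(_Chain(name, strand, diag, off, off + index.k))
    return chains


def _mismatch_prefix(a: str, b: str) -> list[int]:
    """prefix[i] = mismatches between a[:i] and b[:i] (padded as mismatch)."""
    out = [0]
    n = 0
    for i in range(max(len(a), len(b))):
        if i >= len(a) or i >= len(b) or a[i] != b[i]:
            n += 1
        out.append(n)
    return out


def _segment_ref_seq(index: KmerIndex, chain: _Chain, q_from: int, q_to: int) -> str:
    """Reference bases a chain predicts for read offsets [q_from, q_to)."""
    ref = index.refs[chain.ref]
    lo = chain.diag + q_from
    hi = chain.diag + q_to
    if lo < 0 or hi > len(ref):
        return ""
    return ref[lo:hi]


def split_align(
    payload: str,
    index: KmerIndex,
    min_segment: int = 15,
    max_insert: int = 12,
    seed_step: int = 4,
) -> SplitResult:
    """Explain a read as one or two reference segments with a junction.

    Seeds are chained per (reference, strand, diagonal); the two best
    non-overlapping chains define the candidate segments. The exact junction
    is the read offset minimising total mismatches of prefix-vs-segment-1 and
    suffix-vs-segment-2, allowing up to ``max_insert`` untemplated bases in
    between. References may include genome contigs plus donor and vector
    sequences (see :meth:`KmerIndex.from_genome`).
    """
    n = len(payload)
    if n < index.k:
        return SplitResult(unexplained_clip=True)
    chains: list[_Chain] = []
    chains += _chain_seeds(payload, index, "+", seed_step)
    rc = revcomp(payload)
    for ch in _chain_seeds(rc, index, "-", seed_step):
        # express minus-strand chains in read coordinates
        ch.q_lo, ch.q_hi = n - ch.q_hi, n - ch.q_lo
        chains.append(ch)
    chains = [c for c in chains if c.q_hi - c.q_lo >= min_segment]
    if not chains:
        return SplitResult(unexplained_clip=True)
    chains.sort(key=lambda c: (-(c.q_hi - c.q_lo), c.q_lo))
    first = min(chains, key=lambda c: (c.q_lo, -(c.q_hi - c.q_lo)))
    partners = [c for c in chains
                if c is not first and c.q_hi > first.q_hi
                and c.q_lo >= first.q_hi - index.k - 8]
    if not partners:
        seg = _refine_segment(payload, index, first, 0, n)
        covered = first.q_hi - first.q_lo
        return SplitResult(segments=[seg] if seg else [],
                           unexplained_clip=covered < n - max(min_segment, 10)
                           or seg is None)
    second = max(partners, key=lambda c: c.q_hi - c.q_lo)
    return _resolve_junction(payload, index, first, second, max_insert)


def _chain_read_to_ref(chain: _Chain, n: int, q: int) -> int:
    """Map a read offset to a reference position along a chain's diagonal."""
    if chain.strand == "+":
        return chain.diag + q
    # chain.diag was computed on the reverse-complemented read
    return chain.diag + (n - q)


def _refine_segment(payload: str, index: KmerIndex, chain: _Chain,
                    q_from: int, q_to: int) -> Segment | None:
    """Edit-distance verify a chained segment and set exact ref coordinates."""
    seq = payload[q_from:q_to]
    if chain.strand == "-":
        seq = revcomp(seq)
    ref = index.refs[chain.ref]
    if chain.strand == "+":
        anchor = chain.diag + q_from
    else:
        anchor = chain.diag + (len(payload) - q_to)
    lo = max(anchor - 10, 0)
    hi = min(anchor + len(seq) + 10, len(ref))
    hit = _align_window(seq, ref, lo, hi)
    if hit is None:
        return None
    edit, start, end, _ = hit
    return Segment(ref=chain.ref, strand=chain.strand,
                   query_start=q_from, query_end=q_to,
                   ref_start=start, ref_end=end, edit_distance=edit)


def _resolve_junction(payload: str, index: KmerIndex, first: _Chain,
                      second: _Chain, max_insert: int) -> SplitResult:
    n = len(payload)
    j_lo = max(second.q_lo - index.k, first.q_lo + 1, 1)
    j_hi = min(first.q_hi + index.k, second.q_hi - 1, n - 1)
    if j_lo > j_hi:
        j_lo = j_hi = max(min(first.q_hi, n - 1), 1)

    def seg1_ref(j: int) -> str:
        if first.strand == "+":
            return _segment_ref_seq(index, first, 0, j)
        lo = first.diag + (n - j)
        hi = first.diag + n
        ref = index.refs[first.ref]
        return revcomp(ref[max(lo, 0):hi]) if hi <= len(ref) else ""

    def seg2_ref(j: int) -> str:
        if second.strand == "+":
            return _segment_ref_seq(index, second, j, n)
        lo = second.diag
        hi = second.diag + (n - j)
        ref = index.refs[second.ref]
        return revcomp(ref[max(lo, 0):min(hi, len(ref))])

    best = None  # (cost, mismatches, -j1, j1, j2)
    for j1 in range(j_lo, j_hi + 1):
        left = seg1_ref(j1)
        m_left = sum(1 for a, b in zip(payload[:j1], left)
                     if a != b) + abs(j1 - len(left))
        for gap in range(0, max_insert + 1):
            j2 = j1 + gap
            if j2 > n - 1:
                break
            right = seg2_ref(j2)
            m_right = sum(1 for a, b in zip(payload[j2:], right)
                          if a != b) + abs((n - j2) - len(right))
            # affine-style gap: untemplated junction bases are cheaper than
            # forcing them onto a segment as mismatches
            gap_cost = 0.0 if gap == 0 else 1.0 + 0.5 * (gap - 1)
            cost = m_left + m_right + gap_cost
            key = (cost, m_left + m_right, -j1, j1, j2)
            if best is None or key < best:
                best = key
    _, _, _, j1, j2 = best
    seg_a = _refine_segment(payload, index, first, 0, j1)
    seg_b = _refine_segment(payload, index, second, j2, n)
    segments = [s for s in (seg_a, seg_b) if s is not None]
    return SplitResult(
        segments=segments,
        junction_offset=j1 if len(segments) == 2 else None,
        inserted_bases=payload[j1:j2] if len(segments) == 2 else "",
        unexplained_clip=len(segments) < 2,
    )
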