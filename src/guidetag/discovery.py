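"""Off-target site discovery from insert-anchored (tag) viewpoints.

Implements the discovery chain: exact-UMI collapse with a read-count floor,
peak calling over aligned tag-junction reads, near-cognate protospacer
search inside each peak window (mismatches plus a single DNA or RNA bulge,
relaxed NNG/NGN PAM), replicate-level filters, ranking, and an exhaustive
mismatch-only genome scan used as the in-silico prediction counterpart.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import DNA_BASES, GenomicInterval, IUPAC, revcomp

_BASE_CODE = {ord(b): i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


@dataclass
class GuideSpec:
    """A guide RNA spacer plus the PAM/mismatch regime used for discovery.

    ``pam_patterns`` are IUPAC 3-mers accepted immediately 3' of the
    protospacer; the default NNG/NGN union means "a G at PAM position 2 or
    3". ``max_mismatches`` and ``max_bulge`` bound the accepted divergence
    between spacer and genomic site.
    """

    spacer: str
    pam_patterns: tuple[str, ...] = ("NNG", "NGN")
    max_mismatches: int = 6
    max_bulge: int = 1

    def __post_init__(self) -> None:
        self.spacer = self.spacer.upper()
        if not set(self.spacer) <= DNA_BASES:
            raise ValueError("spacer must be plain A/C/G/T")
        lengths = {len(p) for p in self.pam_patterns}
        if lengths != {3}:
            raise ValueError("PAM patterns must all be 3-mers")
        for p in self.pam_patterns:
            if not set(p) <= set(IUPAC):
                raise ValueError(f"invalid IUPAC code in PAM pattern {p!r}")
        if self.max_mismatches < 0 or self.max_bulge not in (0, 1):
            raise ValueError("limits must be non-negative (max_bulge 0 or 1)")


@dataclass
class SiteMatch:
    """A protospacer placement inside a search window.

    Coordinates are 0-based half-open over the window that was searched and
    cover the protospacer only (PAM excluded). ``bulge`` is ``None``, or
    ``("DNA", i)`` for an extra genomic base inserted between spacer
    positions i-1 and i, or ``("RNA", i)`` for spacer base i left unpaired
    (genomic site one base shorter).
    """

    start: int
    end: int
    strand: str
    site_seq: str
    mismatches: int
    bulge: tuple[str, int] | None
    pam: str

    @property
    def bulge_count(self) -> int:
        return 0 if self.bulge is None else 1


def _pam_ok_array(seq_codes: np.ndarray, patterns: Sequence[str]) -> np.ndarray:
    """ok[p] = True if seq[p:p+3] matches any IUPAC pattern."""
    n = len(seq_codes)
    if n < 3:
        return np.zeros(0, dtype=bool)
    ok = np.zeros(n - 2, dtype=bool)
    for pat in patterns:
        m = np.ones(n - 2, dtype=bool)
        for j, code in enumerate(pat):
            allowed = np.array([_BASE_CODE[ord(b)] for b in IUPAC[code]])
            m &= np.isin(seq_codes[j:n - 2 + j], allowed)
        ok |= m
    return ok


def _candidate_matches(seq: str, guide: GuideSpec) -> list[tuple]:
    """All valid placements on one strand of ``seq``.

    Returns tuples (bulges, mismatches, start, glen, bulge_desc) where
    ``glen`` is the genomic footprint of the protospacer (L, L-1 or L+1).
    """
    L = len(guide.spacer)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.array([_BASE_CODE.get(c, 4) for c in codes], dtype=np.uint8)
    spacer = np.array([_BASE_CODE[ord(b)] for b in guide.spacer], dtype=np.uint8)
    pam_ok = _pam_ok_array(codes, guide.pam_patterns)
    out: list[tuple] = []

    def collect(glen: int, mism: np.ndarray, desc) -> None:
        starts = np.arange(len(mism))
        pam_pos = starts + glen
        valid = pam_pos + 3 <= len(seq)
        has_pam = np.zeros(len(mism), dtype=bool)
        has_pam[valid] = pam_ok[pam_pos[valid]]
        keep = (mism <= guide.max_mismatches) & has_pam
        for i in np.nonzero(keep)[0]:
            out.append((0 if desc is None else 1, int(mism[i]), int(i), glen, desc))

    if len(codes) >= L:
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        collect(L, (win != spacer).sum(axis=1), None)
    if guide.max_bulge >= 1:
        # RNA bulge: spacer base b unpaired; genomic footprint L-1
        if len(codes) >= L - 1:
            win = np.lib.stride_tricks.sliding_window_view(codes, L - 1)
            for b in range(1, L - 1):
                sp = np.delete(spacer, b)
                collect(L - 1, (win != sp).sum(axis=1), ("RNA", b))
        # DNA bulge: extra genomic base between spacer positions b-1 and b
        if len(codes) >= L + 1:
            win = np.lib.stride_tricks.sliding_window_view(codes, L + 1)
            for b in range(1, L):
                cols = np.r_[0:b, b + 1:L + 1]
                collect(L + 1, (win[:, cols] != spacer).sum(axis=1), ("DNA", b))
    return out


def search_protospacer(window: str, guide: GuideSpec) -> SiteMatch | None:
    """Best near-cognate protospacer match within a window, both strands.

    A placement is valid when mismatches <= ``guide.max_mismatches``, at
    most ``guide.max_bulge`` bulge, and the 3-mer 3' of the protospacer
    matches an accepted PAM pattern. Candidate bulge positions are interior:
    an RNA bulge may leave spacer base 1..L-2 unpaired; a DNA bulge inserts
    a genomic base at gap 1..L-1. Best = lexicographic minimum of (bulge
    count, mismatches), ties resolved by distance to the window centre, then
    leftmost start, then the + strand.
    """
    window = window.upper()
    W = len(window)
    L = len(guide.spacer)
    if W < L + 2:
        return None
    centre = W / 2
    best: tuple | None = None
    best_match: SiteMatch | None = None
    for strand, seq in (("+", window), ("-", revcomp(window))):
        for bulges, mism, i, glen, desc in _candidate_matches(seq, guide):
            if strand == "+":
                start_w, end_w = i, i + glen
            else:
                start_w, end_w = W - (i + glen), W - i
            dist = abs((start_w + end_w) / 2 - centre)
            key = (bulges, mism, dist, start_w, 0 if strand == "+" else 1)
            if best is None or key < best:
                best = key
                site_seq = seq[i:i + glen]
                best_match = SiteMatch(
                    start=start_w, end=end_w, strand=strand, site_seq=site_seq,
                    mismatches=mism, bulge=desc, pam=seq[i + glen:i + glen + 3],
                )
    return best_match


# ---------------------------------------------------------------------------
# UMI collapse and peak calling
# ---------------------------------------------------------------------------

@dataclass
class UmiExemplar:
    umi: str
    read_id: str
    sequence: str
    read_count: int


def collapse_umis(
    reads: Iterable[tuple[str, str, str]], min_reads: int = 3,
) -> dict[str, UmiExemplar]:
    """Collapse reads sharing a locus into one exemplar per retained UMI.

    ``reads`` yields (umi, read_id, sequence) tuples from a single sample
    and locus. UMIs are compared by exact string equality; a UMI is retained
    only with at least ``min_reads`` supporting reads (suppresses UMI
    singletons created by sequencing error). The exemplar is the most
    frequent sequence in the group, ties broken by first read id.
    """
    groups: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for umi, read_id, seq in reads:
        groups[umi].append((read_id, seq))
    out: dict[str, UmiExemplar] = {}
    for umi, members in groups.items():
        if len(members) < min_reads:
            continue
        counts = Counter(seq for _, seq in members)
        top = max(counts.values())
        winners = {seq for seq, c in counts.items() if c == top}
        read_id, seq = min(
            ((rid, s) for rid, s in members if s in winners), key=lambda t: t[0])
        out[umi] = UmiExemplar(umi=umi, read_id=read_id, sequence=seq,
                               read_count=len(members))
    return out


@dataclass(slots=True)
class TagAlignment:
    """One aligned tag-junction read, reduced to its strand-aware 5' start."""

    sample: str
    viewpoint: str
    umi: str
    read_id: str
    contig: str
    pos5: int
    strand: str
    sequence: str = ""


@dataclass
class Peak:
    """A cluster of tag-junction 5' starts (either strand)."""

    interval: GenomicInterval
    summit: int
    members: list[TagAlignment] = field(default_factory=list)


def call_peaks(alignments: Sequence[TagAlignment], cluster_gap: int = 10,
               flank: int = 25) -> list[Peak]:
    """Single-linkage clustering of 5' start positions into peaks.

    Starts on either strand within ``cluster_gap`` of each other join one
    peak. The peak interval spans the member starts; the downstream search
    window is the span extended by ``flank`` on both sides. The summit is
    the modal start (ties -> smallest coordinate).
    """
    peaks: list[Peak] = []
    by_contig: dict[str, list[TagAlignment]] = defaultdict(list)
    for aln in alignments:
        by_contig[aln.contig].append(aln)
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda a: a.pos5)
        cluster: list[TagAlignment] = []
        for aln in members:
            if cluster and aln.pos5 - cluster[-1].pos5 > cluster_gap:
                peaks.append(_make_peak(contig, cluster))
                cluster = []
            cluster.append(aln)
        if cluster:
            peaks.append(_make_peak(contig, cluster))
    return peaks


def _make_peak(contig: str, cluster: list[TagAlignment]) -> Peak:
    starts = [a.pos5 for a in cluster]
    modal = Counter(starts).most_common()
    top = max(c for _, c in modal)
    summit = min(pos for pos, c in modal if c == top)
    return Peak(
        interval=GenomicInterval(contig, min(starts), max(starts) + 1),
        summit=summit,
        members=list(cluster),
    )


def peak_window(peak: Peak, genome_len: int, flank: int = 25) -> tuple[int, int]:
    """Search window for a peak: member span extended by ``flank``."""
    lo = max(peak.interval.start - flank, 0)
    hi = min(peak.interval.end + flank, genome_len)
    return lo, hi


# ---------------------------------------------------------------------------
# Replicate filters, ranking, prediction, overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateFilter:
    """Per-sample thresholds a site must meet in >= min_samples samples."""

    min_umis: int
    min_reads: int
    min_samples: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.min_samples > self.n_samples:
            raise ValueError("min_samples cannot exceed n_samples")


#: Conservative discovery filter: UMIs >= 5 and reads >= 50 in >= 4 of 6 samples.
FILTER1 = ReplicateFilter(min_umis=5, min_reads=50, min_samples=4, n_samples=6)
#: Relaxed discovery filter: UMIs >= 1 in >= 4 of 6 samples.
FILTER2 = ReplicateFilter(min_umis=1, min_reads=0, min_samples=4, n_samples=6)


def _sample_names(table: pd.DataFrame) -> list[str]:
    samples = [c[len("umi_"):] for c in table.columns if c.startswith("umi_")]
    for s in samples:
        if f"reads_{s}" not in table.columns:
            raise KeyError(f"missing column reads_{s} for sample {s!r}")
    return samples


def apply_replicate_filter(table: pd.DataFrame,
                           filt: ReplicateFilter) -> pd.DataFrame:
    """Keep sites where enough samples individually clear both thresholds."""
    samples = _sample_names(table)
    if len(samples) != filt.n_samples:
        raise KeyError(
            f"table has {len(samples)} sample columns, filter expects "
            f"{filt.n_samples}")
    if table.empty:
        return table.copy()
    passing = sum(
        ((table[f"umi_{s}"] >= filt.min_umis)
         & (table[f"reads_{s}"] >= filt.min_reads)).astype(int)
        for s in samples
    )
    return table.loc[passing >= filt.min_samples].copy()


def rank_and_report(table: pd.DataFrame,
                    on_target: GenomicInterval | None = None,
                    tolerance_bp: int = 10) -> pd.DataFrame:
    """Attach per-sample UMI percentages and rank sites by mean UMI count.

    ``umi_pct_<sample>`` normalises each site's UMIs to the total retained
    UMIs over all reported sites in that sample (so percentages sum to 100
    per sample). Rank is by mean UMI count descending; ties break by
    (contig, start). The on-target row, when identifiable, is flagged.
    """
    if table.empty:
        return table.copy()
    samples = _sample_names(table)
    out = table.copy()
    for s in samples:
        total = out[f"umi_{s}"].sum()
        out[f"umi_pct_{s}"] = (100.0 * out[f"umi_{s}"] / total) if total else 0.0
    out["mean_umi"] = out[[f"umi_{s}" for s in samples]].mean(axis=1)
    out["on_target"] = False
    if on_target is not None:
        near = ((out["contig"] == on_target.contig)
                & ((out["start"] - on_target.start).abs() <= tolerance_bp)
                & (out["mismatches"] == 0))
        out.loc[near, "on_target"] = True
    out = out.sort_values(["mean_umi", "contig", "start"],
                          ascending=[False, True, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def genome_scan(guide: GuideSpec, genome, max_mismatches: int = 3,
                pam_patterns: tuple[str, ...] = ("NGG",)) -> pd.DataFrame:
    """Exhaustive mismatch-only prediction scan of a whole genome.

    Both strands of every contig are scanned for spacer-length windows with
    at most ``max_mismatches`` substitutions (no bulges) followed by an
    accepted PAM (default NGG, the usual prediction-mode motif). Rows are
    ordered by (contig, start, strand).
    """
    L = len(guide.spacer)
    spacer = np.array([_BASE_CODE[ord(b)] for b in guide.spacer], dtype=np.uint8)
    rows = []
    for contig in genome:
        seq = genome[contig]
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            if n < L + 3:
                continue
            codes = np.array([_BASE_CODE.get(c, 4) for c in s.encode()],
                             dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(codes, L)
            mism = (win != spacer).sum(axis=1)
            pam_ok = _pam_ok_array(codes, pam_patterns)
            starts = np.arange(len(mism))
            pam_pos = starts + L
            valid = pam_pos + 3 <= n
            ok = np.zeros(len(mism), dtype=bool)
            ok[valid] = pam_ok[pam_pos[valid]]
            for i in np.nonzero((mism <= max_mismatches) & ok)[0]:
                if strand == "+":
                    start, end = int(i), int(i) + L
                else:
                    start, end = n - int(i) - L, n - int(i)
                rows.append({
                    "contig": contig, "start": start, "end": end,
                    "strand": strand, "site_seq": s[i:i + L],
                    "mismatches": int(mism[i]), "pam": s[i + L:i + L + 3],
                })
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "strand",
                                     "site_seq", "mismatches", "pam"])
    return df.sort_values(["contig", "start", "strand"],
                          kind="stable").reset_index(drop=True)


def overlap_sites(set_a: pd.DataFrame, set_b: pd.DataFrame,
                  tolerance_bp: int = 10) -> dict[str, pd.DataFrame]:
    """Partition two site tables into shared and exclusive sites.

    Sites are paired when their protospacer intervals lie on the same contig
    and strand with starts within ``tolerance_bp``. Each site pairs at most
    once (nearest-start greedy matching).
    """
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for ia, a in set_a.iterrows():
        best = None
        for ib, b in set_b.iterrows():
            if ib in used_b or a["contig"] != b["contig"] \
                    or a["strand"] != b["strand"]:
                continue
            d = abs(int(a["start"]) - int(b["start"]))
            if d <= tolerance_bp and (best is None or d < best[0]):
                best = (d, ib)
        if best is not None:
            used_b.add(best[1])
            pairs.append((ia, best[1]))
    a_idx = [p[0] for p in pairs]
    b_idx = [p[1] for p in pairs]
    return {
        "shared_a": set_a.loc[a_idx],
        "shared_b": set_b.loc[b_idx],
        "a_only": set_a.drop(index=a_idx),
        "b_only": set_b.drop(index=b_idx),
    }
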