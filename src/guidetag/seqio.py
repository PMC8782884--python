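"""Sequence I/O, coordinate conventions, and annotated-oligo parsing.

All internal genomic coordinates are 0-based half-open intervals; the SAM
(1-based) and BED (0-based half-open) conventions are converted only at the
boundary, in :func:`ingest_alignments` and :func:`write_bed`.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
import pysam

DNA_BASES = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")

#: IUPAC nucleotide ambiguity codes, used for PAM patterns only -- reads may
#: contain N but no other ambiguity code.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(observed: str, pattern: str) -> bool:
    """True if ``observed`` (concrete bases) satisfies an IUPAC ``pattern``."""
    if len(observed) != len(pattern):
        return False
    return all(o in IUPAC.get(p, "") for o, p in zip(observed, pattern))


class ParseError(ValueError):
    """Raised when an annotated oligo string contains an unknown token."""


@dataclass
class SequenceRecord:
    """A single read or reference sequence.

    ``quality`` is a Phred+33 string of the same length as ``sequence`` when
    present. ``mate`` distinguishes the two reads of a pair and merged reads.
    """

    id: str
    sequence: str
    quality: str | None = None
    mate: str = "R1"  # one of R1 / R2 / merged

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= READ_ALPHABET:
            bad = sorted(set(self.sequence) - READ_ALPHABET)
            raise ValueError(f"non-DNA characters in sequence {self.id!r}: {bad}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"quality/sequence length mismatch for {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def distance(self, other: "GenomicInterval") -> float:
        """Gap between two intervals; 0 if overlapping, inf across contigs."""
        if self.contig != other.contig:
            return float("inf")
        return max(self.start, other.start) - min(self.end, other.end) \
            if (self.end <= other.start or other.end <= self.start) else 0


class GenomeRef:
    """An in-memory reference genome: ordered mapping contig name -> sequence."""

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            clean[name] = seq
        self.contigs = clean
        self.lengths = {name: len(seq) for name, seq in clean.items()}

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def fetch(self, iv: GenomicInterval) -> str:
        """Sequence of an interval, reverse-complemented for '-' strand."""
        seq = self.contigs[iv.contig][iv.start:iv.end]
        return revcomp(seq) if iv.strand == "-" else seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeRef":
        with _open_text(path) as handle:
            contigs: dict[str, str] = {}
            name, chunks = None, []
            for line in handle:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        contigs[name] = "".join(chunks)
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
            if name is not None:
                contigs[name] = "".join(chunks)
        return cls(contigs)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as out:
            for name, seq in self.contigs.items():
                out.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotated synthesis oligos
# ---------------------------------------------------------------------------

@dataclass
class OligoSpec:
    """A synthesis oligo: raw annotated string, bare sequence, modifications.

    Modifications are recorded as ``(position, kind)`` where ``position``
    indexes the base in ``clean`` that carries (or precedes, for backbone
    linkages) the modification. Recognised kinds: ``5prime_phosphate``,
    ``biotin`` (5' or internal), ``phosphorothioate``.
    """

    raw: str
    clean: str
    modifications: list[tuple[int, str]] = field(default_factory=list)


_OLIGO_PREFIX = re.compile(r"^(?:5'-|5′-|5-)")


def parse_oligo(raw: str) -> OligoSpec:
    """Parse an annotated synthesis string into bare DNA plus modifications.

    Handles the notation used on synthesis order sheets: an optional ``5'-``
    prefix, ``P-`` for 5' phosphorylation, ``biotin-`` for a 5' biotin,
    ``(biotin)`` for an internal biotin, and ``*`` for a phosphorothioate
    bond between the flanking bases.
    """
    if not raw:
        raise ParseError("empty oligo string")
    s = _OLIGO_PREFIX.sub("", raw.strip())
    mods: list[tuple[int, str]] = []
    if s.startswith("P-"):
        mods.append((0, "5prime_phosphate"))
        s = s[2:]
    elif s.lower().startswith("biotin-"):
        mods.append((0, "biotin"))
        s = s[len("biotin-"):]
    clean: list[str] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in DNA_BASES:
            clean.append(ch)
            i += 1
        elif ch == "*":
            if not clean:
                raise ParseError("phosphorothioate '*' before any base")
            mods.append((len(clean) - 1, "phosphorothioate"))
            i += 1
        elif ch == "(":
            close = s.find(")", i)
            token = s[i + 1:close] if close != -1 else s[i:]
            if close != -1 and token.lower() == "biotin":
                mods.append((max(len(clean) - 1, 0), "biotin"))
                i = close + 1
            else:
                raise ParseError(f"unrecognized annotation token {token!r}")
        else:
            raise ParseError(f"unrecognized annotation token {ch!r}")
    if not clean:
        raise ParseError("oligo contains no bases")
    return OligoSpec(raw=raw, clean="".join(clean), modifications=mods)


@dataclass
class DuplexDescriptor:
    """Result of annealing two oligos: duplex length and end structure."""

    is_duplex: bool
    length: int = 0
    overhang_5: int = 0
    overhang_3: int = 0

    @property
    def blunt(self) -> bool:
        return self.is_duplex and self.overhang_5 == 0 and self.overhang_3 == 0


def duplex_check(a: OligoSpec, b: OligoSpec) -> DuplexDescriptor:
    """Check whether two parsed oligos anneal into a duplex.

    A full blunt duplex requires ``b.clean`` to be the exact reverse
    complement of ``a.clean``. Single-ended overhangs (one strand extending
    past the other) are detected by substring containment of the reverse
    complement; anything else is flagged as non-complementary.
    """
    rc_b = revcomp(b.clean)
    if rc_b == a.clean:
        return DuplexDescriptor(is_duplex=True, length=len(a.clean))
    longer, shorter = (a.clean, rc_b) if len(a.clean) >= len(rc_b) else (rc_b, a.clean)
    pos = longer.find(shorter)
    if pos != -1:
        return DuplexDescriptor(
            is_duplex=True,
            length=len(longer),
            overhang_5=pos,
            overhang_3=len(longer) - pos - len(shorter),
        )
    return DuplexDescriptor(is_duplex=False)


# ---------------------------------------------------------------------------
# FASTQ / FASTA streaming (gzip-transparent)
# ---------------------------------------------------------------------------

def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path, mate: str = "R1") -> Iterator[SequenceRecord]:
    """Stream FASTQ records (plain or gzip) as :class:`SequenceRecord`."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield SequenceRecord(
                id=entry.name, sequence=entry.sequence,
                quality=entry.quality, mate=mate,
            )


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write records as FASTQ (gzip if the path ends in .gz); returns count."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        for rec in records:
            qual = rec.quality or "I" * len(rec.sequence)
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM ingest (external-aligner boundary)
# ---------------------------------------------------------------------------

_CIGAR_CODES = "MIDNSHP=X"


@dataclass
class IngestStats:
    total: int = 0
    ingested: int = 0
    unmapped: int = 0
    malformed: int = 0


def ingest_alignments(sam_path: str | Path, stats: IngestStats | None = None):
    """Read a text SAM file into internal alignments.

    1-based SAM positions become 0-based half-open intervals; the CIGAR is
    preserved as an operation list ('='/'X' normalised to M). Unmapped and
    malformed records are dropped and counted in ``stats``.
    """
    from .align import Alignment  # deferred: align builds on seqio types

    stats = stats if stats is not None else IngestStats()
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            stats.total += 1
            if rec.is_unmapped or rec.reference_name is None:
                stats.unmapped += 1
                continue
            if not rec.cigartuples:
                stats.malformed += 1
                continue
            cigar: list[tuple[str, int]] = []
            ref_span = 0
            ok = True
            for op, length in rec.cigartuples:
                code = _CIGAR_CODES[op]
                if code in "=X":
                    code = "M"
                if code not in "MIDS":
                    ok = False
                    break
                if code in "MD":
                    ref_span += length
                cigar.append((code, length))
            if not ok or ref_span == 0:
                stats.malformed += 1
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(Alignment(
                read_id=rec.query_name,
                interval=GenomicInterval(
                    rec.reference_name, rec.reference_start,
                    rec.reference_start + ref_span,
                    "-" if rec.is_reverse else "+",
                ),
                cigar=cigar,
                edit_distance=int(nm),
            ))
    return out, stats


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = [
    "rank", "contig", "start", "end", "strand", "site_seq",
    "mismatches", "bulge", "pam",
]


def write_site_table(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table TSV with fixed leading columns and stable order.

    Rows are ordered by rank then (contig, start); per-sample count columns
    follow the fixed columns in their existing order.
    """
    fixed = [c for c in SITE_TABLE_COLUMNS if c in sites.columns]
    extra = [c for c in sites.columns if c not in fixed]
    if sites.empty:
        pd.DataFrame(columns=fixed + extra).to_csv(path, sep="\t", index=False)
        return
    sort_by = [c for c in ("rank", "contig", "start") if c in sites.columns]
    out = sites.sort_values(sort_by, kind="stable")[fixed + extra]
    out.to_csv(path, sep="\t", index=False)


def write_bed(sites: pd.DataFrame, path: str | Path, name_col: str = "name",
              score_col: str | None = None) -> None:
    """Write BED6 (0-based half-open) from a table with interval columns."""
    with open(path, "w") as out:
        if sites.empty:
            return
        ordered = sites.sort_values(["contig", "start"], kind="stable")
        for i, row in enumerate(ordered.itertuples(index=False)):
            d = row._asdict()
            name = d.get(name_col, f"site_{i + 1}")
            score = d.get(score_col, 0) if score_col else 0
            out.write(f"{d['contig']}\t{d['start']}\t{d['end']}\t{name}"
                      f"\t{score:g}\t{d.get('strand', '+')}\n")
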