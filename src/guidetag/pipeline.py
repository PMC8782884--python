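"""End-to-end workflows: discover, outcomes, rearrange, predict, simulate.

These functions chain the library modules into the canonical analyses and
are what the command-line entry points call. They accept in-memory objects
(read-pair iterables, :class:`GenomeRef`, :class:`GuideSpec`) so the same
code path serves tests, scripts and the CLI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .align import Alignment, KmerIndex, align_read, five_prime_start
from .discovery import (GuideSpec, Peak, ReplicateFilter, TagAlignment,
                        apply_replicate_filter, call_peaks, collapse_umis,
                        genome_scan, peak_window, rank_and_report,
                        search_protospacer)
from .outcomes import (DONOR_REF, VECTOR_REF, Classification, EditClass,
                       LocusSpec, OutcomeTable, tabulate_outcomes)
from .preprocess import (INSERT_VIEWPOINTS, LibraryLayout, PreprocessStats,
                         process_pair)
from .rearrange import (TranslocationEvent, adjust_events, attach_rates,
                        call_translocations, events_to_table, group_test)
from .seqio import GenomeRef, GenomicInterval, SequenceRecord, read_fastq


def read_pairs_from_fastq(r1_path, r2_path):
    """Zip two FASTQ files into read pairs (mate order preserved)."""
    return zip(read_fastq(r1_path, "R1"), read_fastq(r2_path, "R2"))


@dataclass
class DiscoveryResult:
    sites: pd.DataFrame            # filtered + ranked site table
    all_sites: pd.DataFrame        # pre-filter site table
    peaks: list[Peak]
    stats: PreprocessStats
    n_aligned: int = 0


def run_discover(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    genome: GenomeRef,
    guide: GuideSpec,
    layout: LibraryLayout,
    barcodes: dict[str, str],
    replicate_filter: ReplicateFilter | None = None,
    on_target: GenomicInterval | None = None,
    min_umi_reads: int = 3,
    cluster_gap: int = 10,
    flank: int = 25,
    index: KmerIndex | None = None,
    external_alignments: dict[str, Alignment] | None = None,
) -> DiscoveryResult:
    """Tag-anchored off-target discovery from insert-viewpoint read pairs.

    Preprocess -> align -> peak call -> per-peak UMI collapse (read-count
    floor ``min_umi_reads``) -> protospacer search in each peak window ->
    replicate filter -> ranked site table with per-sample UMI percentages.
    Evidence from both insert viewpoints is pooled per site.

    ``external_alignments`` (read id -> alignment, e.g. from
    :func:`guidetag.seqio.ingest_alignments` of an external aligner's SAM)
    takes precedence over the built-in engine when supplied; reads absent
    from the mapping are treated as unaligned.
    """
    stats = PreprocessStats()
    if external_alignments is None:
        index = index or KmerIndex.from_genome(genome)
    aligned: list[TagAlignment] = []
    for r1, r2 in pairs:
        tagged = process_pair(r1, r2, layout, barcodes, stats)
        if tagged is None or tagged.viewpoint not in INSERT_VIEWPOINTS:
            continue
        if external_alignments is not None:
            aln = external_alignments.get(tagged.provenance)
        else:
            aln = align_read(tagged.payload, index, read_id=tagged.provenance)
        if aln is None:
            continue
        aligned.append(TagAlignment(
            sample=tagged.sample, viewpoint=tagged.viewpoint, umi=tagged.umi,
            read_id=tagged.provenance, contig=aln.interval.contig,
            pos5=five_prime_start(aln), strand=aln.strand))
    peaks = call_peaks(aligned, cluster_gap=cluster_gap, flank=flank)
    samples = sorted(barcodes)
    rows = []
    for peak in peaks:
        lo, hi = peak_window(peak, genome.lengths[peak.interval.contig],
                             flank=flank)
        match = search_protospacer(genome[peak.interval.contig][lo:hi], guide)
        if match is None:
            continue
        row = {
            "contig": peak.interval.contig,
            "start": lo + match.start,
            "end": lo + match.end,
            "strand": match.strand,
            "site_seq": match.site_seq,
            "mismatches": match.mismatches,
            "bulge": "none" if match.bulge is None
                     else f"{match.bulge[0]}:{match.bulge[1]}",
            "pam": match.pam,
        }
        for sample in samples:
            members = [m for m in peak.members if m.sample == sample]
            retained = collapse_umis(
                ((m.umi, m.read_id, "") for m in members),
                min_reads=min_umi_reads)
            row[f"umi_{sample}"] = len(retained)
            row[f"reads_{sample}"] = len(members)
        rows.append(row)
    all_sites = pd.DataFrame(rows)
    if all_sites.empty:
        cols = ["contig", "start", "end", "strand", "site_seq", "mismatches",
                "bulge", "pam"] + [f"umi_{s}" for s in samples] \
            + [f"reads_{s}" for s in samples]
        all_sites = pd.DataFrame(columns=cols)
    filtered = all_sites
    if replicate_filter is not None:
        filtered = apply_replicate_filter(all_sites, replicate_filter)
    ranked = rank_and_report(filtered, on_target=on_target)
    return DiscoveryResult(sites=ranked, all_sites=all_sites, peaks=peaks,
                           stats=stats, n_aligned=len(aligned))


@dataclass
class OutcomesResult:
    tables: dict[str, OutcomeTable]                    # per sample
    classifications: list[tuple[str, Classification]]  # (sample, result)
    stats: PreprocessStats
    exemplars_per_sample: dict[str, int] = field(default_factory=dict)


def run_outcomes(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    genome: GenomeRef,
    locus: LocusSpec,
    layout: LibraryLayout,
    barcodes: dict[str, str],
    donor: str,
    vector: str = "",
    min_umi_reads: int = 3,
    viewpoint: str = "Locus_F",
) -> OutcomesResult:
    """UDiTaS-style per-UMI outcome classification at one locus viewpoint."""
    stats = PreprocessStats()
    extra = {DONOR_REF: donor}
    if vector:
        extra[VECTOR_REF] = vector
    index = KmerIndex.from_genome(genome, extra=extra)
    by_sample: dict[str, list[tuple[str, str, str]]] = {s: [] for s in barcodes}
    for r1, r2 in pairs:
        tagged = process_pair(r1, r2, layout, barcodes, stats)
        if tagged is None or tagged.viewpoint != viewpoint:
            continue
        by_sample[tagged.sample].append(
            (tagged.umi, tagged.provenance, tagged.payload))
    tables: dict[str, OutcomeTable] = {}
    classifications: list[tuple[str, Classification]] = []
    exemplar_counts: dict[str, int] = {}
    for sample in sorted(by_sample):
        exemplars = collapse_umis(by_sample[sample], min_reads=min_umi_reads)
        exemplar_counts[sample] = len(exemplars)
        sample_classes = []
        for umi in sorted(exemplars):
            cls = classify_payload(exemplars[umi].sequence, index, locus)
            sample_classes.append(cls)
            classifications.append((sample, cls))
        tables[sample] = tabulate_outcomes(
            sample_classes, sample=sample, viewpoint=viewpoint,
            locus=locus.contig)
    return OutcomesResult(tables=tables, classifications=classifications,
                          stats=stats, exemplars_per_sample=exemplar_counts)


def classify_payload(payload: str, index: KmerIndex,
                     locus: LocusSpec) -> Classification:
    from .outcomes import classify_exemplar
    return classify_exemplar(payload, index, locus)


@dataclass
class RearrangeResult:
    events: list[TranslocationEvent]
    table: pd.DataFrame
    novel_partners: int


def run_rearrange(
    outcomes: OutcomesResult,
    known_sites: pd.DataFrame,
    anchor: GenomicInterval,
    anchor_cut: int,
    treated: Sequence[str],
    controls: Sequence[str],
    tolerance_bp: int = 25,
) -> RearrangeResult:
    """Aggregate translocation candidates and test treated vs control rates.

    Rates use edited (non-wild-type) UMIs as the denominator. Significance
    is Welch's t on arcsine-transformed rates against the control samples,
    BH-adjusted across events; without controls the test is refused and the
    events carry no p-values.
    """
    candidates = [(s, c) for s, c in outcomes.classifications
                  if c.edit_class is EditClass.translocation_candidate]
    events, novel = call_translocations(
        candidates, known_sites, anchor, anchor_cut, tolerance_bp=tolerance_bp)
    edited = {s: t.edited_total for s, t in outcomes.tables.items()}
    attach_rates(events, edited)
    if controls:
        results = []
        for ev in events:
            res = group_test([ev.rates.get(s, 0.0) for s in treated],
                             [ev.rates.get(s, 0.0) for s in controls])
            results.append(res)
        adjust_events(events, results)
    return RearrangeResult(events=events, table=events_to_table(events),
                           novel_partners=len(novel))


def run_predict(genome: GenomeRef, guide: GuideSpec,
                max_mismatches: int = 3,
                pam_patterns: tuple[str, ...] = ("NGG",)) -> pd.DataFrame:
    """Exhaustive in-silico off-target prediction (mismatch-only, NGG)."""
    return genome_scan(guide, genome, max_mismatches=max_mismatches,
                       pam_patterns=pam_patterns)


def write_provenance(outdir: str | Path, seed: int | None,
                     config: dict) -> Path:
    """Machine-readable run record: config hash, seed, package version."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(blob),
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
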