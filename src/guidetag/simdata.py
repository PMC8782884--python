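"""Seeded synthetic genomes and tagmentation read libraries with ground truth.

The generator emulates the four-viewpoint library design (two locus-anchored
UDiTaS-style viewpoints, two tag-anchored insert viewpoints): a toy genome
with planted on- and off-target protospacer sites, dsODN tag integration at
each site at a configured per-molecule rate, editing-outcome mixtures at the
target locus (indels, large deletions, donor insertions, translocations),
random UMIs, PCR duplication from a truncated geometric distribution,
and substitution-only sequencing error. Every stream of randomness comes
from one seeded generator, so output is byte-identical per (seed, truth).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .discovery import GuideSpec, search_protospacer
from .outcomes import EditClass, blunt_cut
from .preprocess import LibraryLayout
from .seqio import GenomeRef, SequenceRecord, revcomp, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_toy_genome(seed: int, size: int = 100_000,
                    contigs: int = 2) -> GenomeRef:
    """Uniform random DNA split over contigs named chrS1, chrS2, ..."""
    rng = np.random.default_rng(seed)
    per = size // contigs
    out = {}
    for i in range(contigs):
        n = per if i < contigs - 1 else size - per * (contigs - 1)
        out[f"chrS{i + 1}"] = rng.choice(_BASES, size=n).tobytes().decode()
    return GenomeRef(out)


@dataclass
class SiteDescriptor:
    """A protospacer site to plant: divergence from the guide plus rates.

    ``bulge`` is None, ("DNA", gap) for an extra genomic base, or
    ("RNA", pos) for an unpaired spacer base, with the same interior-
    position convention as the discovery search. ``integration_rate`` is
    the per-molecule probability that this site carries a tag in the
    insert-viewpoint library.
    """

    name: str
    mismatches: int = 0
    bulge: tuple[str, int] | None = None
    pam: str = "TGG"
    integration_rate: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.integration_rate <= 1 or not 0 <= self.indel_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class PlantedSite:
    descriptor: SiteDescriptor
    contig: str
    start: int
    end: int
    strand: str
    site_seq: str
    cut_site: int

    @property
    def name(self) -> str:
        return self.descriptor.name


def _mutate_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def _site_sequence(rng, guide: GuideSpec, desc: SiteDescriptor) -> str:
    """Genomic protospacer sequence realising a descriptor (without PAM)."""
    spacer = list(guide.spacer)
    L = len(spacer)
    if desc.bulge and desc.bulge[0] == "RNA":
        b = desc.bulge[1]
        if not 1 <= b <= L - 2:
            raise ValueError("RNA bulge position must be interior (1..L-2)")
        site = spacer[:b] + spacer[b + 1:]
        mutable = list(range(len(site)))
    elif desc.bulge and desc.bulge[0] == "DNA":
        b = desc.bulge[1]
        if not 1 <= b <= L - 1:
            raise ValueError("DNA bulge gap must be interior (1..L-1)")
        site = spacer[:b] + [ "ACGT"[rng.integers(4)] ] + spacer[b:]
        mutable = [i for i in range(len(site)) if i != b]
    else:
        site = spacer[:]
        mutable = list(range(L))
    if desc.mismatches > len(mutable):
        raise ValueError("more mismatches requested than spacer positions")
    positions = rng.choice(np.array(mutable), size=desc.mismatches,
                           replace=False)
    for p in positions:
        site[p] = _mutate_base(rng, site[p])
    return "".join(site)


def plant_sites(
    genome: GenomeRef,
    guide: GuideSpec,
    descriptors: Sequence[SiteDescriptor],
    seed: int,
    min_gap: int = 600,
    edge_margin: int = 1_000,
    max_retries: int = 40,
) -> tuple[GenomeRef, list[PlantedSite]]:
    """Write each descriptor's site into the genome and verify it.

    Placement is random, non-overlapping (``min_gap`` apart) and away from
    contig edges. After writing, :func:`discovery.search_protospacer` is run
    on the local window and must reproduce the descriptor's mismatch count
    and bulge exactly (the random background, or a bulge-free re-reading of
    a bulged site, can otherwise shadow it); failures are retried at a new
    position — and, for bulged descriptors, with the bulge re-drawn at
    another interior position, since for self-similar spacers some bulge
    placements always admit a cheaper bulge-free interpretation — up to
    ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    contigs = {name: list(genome[name]) for name in genome}
    placed: list[PlantedSite] = []
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in genome}
    L = len(guide.spacer)
    for desc in descriptors:
        for attempt in range(max_retries):
            if desc.bulge is not None and attempt >= max_retries // 4:
                kind = desc.bulge[0]
                hi = L - 1 if kind == "RNA" else L
                desc = replace(desc, bulge=(kind, int(rng.integers(1, hi))))
            site_seq = _site_sequence(rng, guide, desc)
            full = site_seq + desc.pam
            strand = "+" if rng.random() < 0.5 else "-"
            contig = list(genome)[rng.integers(len(genome))]
            clen = len(contigs[contig])
            pos = int(rng.integers(edge_margin, clen - edge_margin - len(full)))
            span = (pos - min_gap, pos + len(full) + min_gap)
            if any(a < span[1] and span[0] < b for a, b in occupied[contig]):
                continue
            written = full if strand == "+" else revcomp(full)
            contigs[contig][pos:pos + len(full)] = list(written)
            window_lo = max(pos - 30, 0)
            window = "".join(contigs[contig][window_lo:pos + len(full) + 30])
            hit = search_protospacer(window, guide)
            ok = (hit is not None
                  and hit.mismatches == desc.mismatches
                  and (hit.bulge is None) == (desc.bulge is None)
                  and (desc.bulge is None or hit.bulge[0] == desc.bulge[0])
                  and hit.strand == strand
                  and window_lo + hit.start == (pos if strand == "+"
                                                else pos + 3))
            if not ok:
                contigs[contig][pos:pos + len(full)] = list(
                    genome[contig][pos:pos + len(full)])
                continue
            occupied[contig].append((pos, pos + len(full)))
            if strand == "+":
                start, end = pos, pos + len(site_seq)
            else:
                start, end = pos + 3, pos + len(full)
            placed.append(PlantedSite(
                descriptor=desc, contig=contig, start=start, end=end,
                strand=strand, site_seq=site_seq,
                cut_site=blunt_cut(start, end, strand)))
            break
        else:
            raise RuntimeError(
                f"could not place site {desc.name!r} after {max_retries} tries")
    new_genome = GenomeRef({name: "".join(seq) for name, seq in contigs.items()})
    return new_genome, placed


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def make_barcodes(rng, n: int, length: int = 8, min_dist: int = 3) -> list[str]:
    """Random sample barcodes with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    while len(out) < n:
        cand = rng.choice(_BASES, size=length).tobytes().decode()
        if all(sum(a != b for a, b in zip(cand, x)) >= min_dist for x in out):
            out.append(cand)
    return out


@dataclass
class SimTruth:
    """Full specification of a simulated experiment plus its ground truth."""

    seed: int
    genome: GenomeRef
    guide: GuideSpec
    sites: list[PlantedSite]
    samples: dict[str, str]                  # sample name -> barcode
    layout: LibraryLayout
    donor: str
    vector: str = ""
    reads_per_sample: int = 50_000           # insert-viewpoint depth target
    locus_molecules: int = 5_000             # UMIs per sample at the locus
    locus_mix: dict[EditClass, float] = field(default_factory=lambda: {
        EditClass.wild_type: 0.55,
        EditClass.donor_forward: 0.25,
        EditClass.small_indel_sub: 0.15,
        EditClass.large_del_ins: 0.05,
    })
    translocation_rates: dict[str, float] = field(default_factory=dict)
    control_samples: tuple[str, ...] = ()   # no translocations planted here
    deletion_length_range: tuple[int, int] = (60, 1_500)
    read_length: int = 110
    primer_length: int = 20
    primer_offset: int = 60            # distance from cut to locus primer 5' end
    tag_prefix_length: int = 16
    pcr_geom_p: float = 0.35
    pcr_max: int = 12
    fixed_duplicates: int | None = None  # overrides the geometric draw
    error_rate: float = 0.002
    umi_n_rate: float = 0.001
    mispriming_rate: float = 0.02

    def __post_init__(self) -> None:
        if abs(sum(self.locus_mix.values()) - 1.0) > 1e-9:
            raise ValueError("locus class mixture must sum to 1")
        for r in self.translocation_rates.values():
            if not 0 <= r <= 1:
                raise ValueError("translocation rates must lie in [0, 1]")

    @property
    def on_target(self) -> PlantedSite:
        return self.sites[0]

    def site(self, name: str) -> PlantedSite:
        return next(s for s in self.sites if s.name == name)


def default_layout(donor: str, on_target: PlantedSite, genome: GenomeRef,
                   primer_length: int = 20,
                   primer_offset: int = 60,
                   tag_prefix_length: int = 16) -> LibraryLayout:
    """Library layout for a simulated experiment.

    Locus primers flank the on-target cut at ``primer_offset``; insert
    viewpoints expect the residual dsODN tag end (``tag_prefix_length``
    bases) at the start of the trimmed read.
    """
    cut = on_target.cut_site
    ref = genome[on_target.contig]
    return LibraryLayout(
        viewpoint_primers={
            "Locus_F": ref[cut - primer_offset:cut - primer_offset + primer_length],
            "Locus_R": revcomp(ref[cut + primer_offset - primer_length:
                                   cut + primer_offset]),
        },
        tag_prefixes={
            "Insert_F": donor[-tag_prefix_length:],
            "Insert_R": revcomp(donor)[-tag_prefix_length:],
        },
    )


def truncated_geometric_mean(p: float, cap: int) -> float:
    ks = np.arange(1, cap + 1)
    pmf = (1 - p) ** (ks - 1) * p
    pmf[-1] += (1 - p) ** cap  # mass above the cap collapses onto it
    return float((ks * pmf).sum())


def _apply_errors(rng, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=n_err, replace=False)
    arr[pos] = _BASES[(np.searchsorted(_BASES, arr[pos]) +
                       rng.integers(1, 4, size=n_err)) % 4]
    return arr.tobytes().decode()


def _random_umi(rng, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


class _MoleculeWriter:
    """Expands molecules into PCR-duplicated, error-bearing read pairs."""

    def __init__(self, truth: SimTruth, rng):
        self.truth = truth
        self.rng = rng
        self.pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
        self._counter = itertools.count()

    def emit(self, sample: str, viewpoint: str, payload_r1: str,
             umi: str | None = None, duplicates: int | None = None) -> str:
        t, rng = self.truth, self.rng
        umi = umi or _random_umi(rng, t.layout.umi_length)
        barcode = t.samples[sample]
        if duplicates is None:
            duplicates = t.fixed_duplicates if t.fixed_duplicates is not None \
                else int(min(rng.geometric(t.pcr_geom_p), t.pcr_max))
        r2_base = umi + barcode + revcomp(payload_r1)[:t.read_length - 16]
        mol_id = next(self._counter)
        for d in range(duplicates):
            r1_seq = _apply_errors(rng, payload_r1[:t.read_length], t.error_rate)
            r2_seq = _apply_errors(rng, r2_base, t.error_rate)
            if rng.random() < t.umi_n_rate:
                i = int(rng.integers(t.layout.umi_length))
                r2_seq = r2_seq[:i] + "N" + r2_seq[i + 1:]
            rid = f"mol{mol_id}:{sample}:{viewpoint}:{d}"
            self.pairs.append((
                SequenceRecord(rid, r1_seq, None, "R1"),
                SequenceRecord(rid, r2_seq, None, "R2"),
            ))
        return umi


def simulate_insert_library(truth: SimTruth
                            ) -> tuple[list[tuple[SequenceRecord, SequenceRecord]],
                                       pd.DataFrame]:
    """Insert-viewpoint (tag-anchored) read pairs plus the molecule truth.

    Per sample, a tagmented-molecule budget is derived from the read depth
    target and the mean PCR duplication; each planted site acquires tag
    integrations as Binomial(budget, integration_rate), split evenly at
    random between the two insert viewpoints. Mispriming molecules (no tag)
    are added at ``mispriming_rate``. The truth table records planted
    molecule counts per (sample, site).
    """
    rng = np.random.default_rng(truth.seed)
    writer = _MoleculeWriter(truth, rng)
    mean_dup = truncated_geometric_mean(truth.pcr_geom_p, truth.pcr_max)
    budget = max(int(truth.reads_per_sample / mean_dup), 1)
    tag_len = len(truth.layout.tag_prefixes["Insert_F"])
    genomic_len = truth.read_length - tag_len
    rows = []
    for sample in truth.samples:
        for site in truth.sites:
            rate = site.descriptor.integration_rate
            if rate <= 0:
                continue
            n_mol = int(rng.binomial(budget, rate))
            ref = truth.genome[site.contig]
            cut = site.cut_site
            for _ in range(n_mol):
                if rng.random() < 0.5:
                    vp = "Insert_F"
                    genomic = ref[cut:cut + genomic_len]
                else:
                    vp = "Insert_R"
                    genomic = revcomp(ref[max(cut - genomic_len, 0):cut])
                payload = truth.layout.tag_prefixes[vp] + genomic
                writer.emit(sample, vp, payload)
            rows.append({"sample": sample, "site": site.name,
                         "contig": site.contig, "cut_site": cut,
                         "integration_rate": rate, "molecules": n_mol})
        n_misprime = int(rng.binomial(budget, truth.mispriming_rate))
        for _ in range(n_misprime):
            contig = list(truth.genome)[rng.integers(len(truth.genome))]
            ref = truth.genome[contig]
            pos = int(rng.integers(0, len(ref) - truth.read_length))
            writer.emit(sample, "Insert_F", ref[pos:pos + truth.read_length])
    truth_table = pd.DataFrame(
        rows, columns=["sample", "site", "contig", "cut_site",
                       "integration_rate", "molecules"])
    return writer.pairs, truth_table


def simulate_locus_library(truth: SimTruth, viewpoint: str = "Locus_F"
                           ) -> tuple[list[tuple[SequenceRecord, SequenceRecord]],
                                      pd.DataFrame]:
    """Locus-viewpoint (UDiTaS-style) read pairs plus per-molecule truth.

    Each of ``locus_molecules`` molecules per sample draws an editing class
    from ``locus_mix``; translocation molecules to named partner sites are
    carved out of the edited classes at ``translocation_rates`` (expressed
    as a fraction of edited molecules). The truth table carries one row per
    molecule with its class and, where applicable, deletion length or
    translocation partner.
    """
    rng = np.random.default_rng(truth.seed + 1)
    writer = _MoleculeWriter(truth, rng)
    on = truth.on_target
    ref = truth.genome[on.contig]
    cut = on.cut_site
    primer = truth.layout.viewpoint_primers[viewpoint]
    if viewpoint != "Locus_F":
        raise NotImplementedError("locus simulation uses the Locus_F viewpoint")
    arm_start = cut - truth.primer_offset + truth.primer_length
    payload_len = truth.read_length
    classes = list(truth.locus_mix)
    probs = np.array([truth.locus_mix[c] for c in classes])
    rows = []
    for sample in truth.samples:
        draws = rng.choice(len(classes), size=truth.locus_molecules, p=probs)
        for d in draws:
            cls = classes[d]
            partner = None
            del_len = 0
            # translocations replace a fraction of edited molecules
            if cls is not EditClass.wild_type and truth.translocation_rates \
                    and sample not in truth.control_samples:
                for pname, prate in truth.translocation_rates.items():
                    if rng.random() < prate:
                        cls = EditClass.translocation_candidate
                        partner = pname
                        break
            left_arm = ref[arm_start:cut]
            room = payload_len - len(primer) - len(left_arm)
            if cls is EditClass.wild_type:
                payload = ref[arm_start:arm_start + payload_len]
            elif cls is EditClass.small_indel_sub:
                del_len = int(rng.integers(1, 25))
                payload = left_arm + ref[cut + del_len:
                                         cut + del_len + room]
            elif cls is EditClass.large_del_ins:
                del_len = int(rng.integers(*truth.deletion_length_range))
                payload = left_arm + ref[cut + del_len:cut + del_len + room]
            elif cls is EditClass.donor_forward:
                payload = left_arm + (truth.donor * 3)[:room]
            elif cls is EditClass.donor_reverse:
                payload = left_arm + (revcomp(truth.donor) * 3)[:room]
            elif cls is EditClass.vector_insertion:
                payload = left_arm + truth.vector[:room]
            elif cls is EditClass.translocation_candidate:
                psite = truth.site(partner)
                pref = truth.genome[psite.contig]
                payload = left_arm + pref[psite.cut_site:psite.cut_site + room]
            else:
                payload = ref[arm_start:arm_start + payload_len]
            umi = writer.emit(sample, viewpoint, primer + payload)
            rows.append({"sample": sample, "umi": umi, "class": cls.value,
                         "deletion_length": del_len,
                         "partner": partner or ""})
    truth_table = pd.DataFrame(
        rows, columns=["sample", "umi", "class", "deletion_length", "partner"])
    return writer.pairs, truth_table


def write_library(pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
                  outdir: str | Path, prefix: str = "library",
                  gzip_out: bool = False) -> tuple[Path, Path]:
    """Write read pairs as a FASTQ pair; returns (r1_path, r2_path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_out else ".fastq"
    r1_path = outdir / f"{prefix}_R1{ext}"
    r2_path = outdir / f"{prefix}_R2{ext}"
    pairs = list(pairs)
    write_fastq((p[0] for p in pairs), r1_path)
    write_fastq((p[1] for p in pairs), r2_path)
    return r1_path, r2_path


#: Default tag-integration rates of the planted off-target sites, spanning
#: the 0.5-10% per-molecule range the discovery filters are designed around.
DEFAULT_OFFTARGET_RATES = (0.10, 0.08, 0.05, 0.04, 0.02, 0.01, 0.0075, 0.005)

#: Mismatch/bulge/PAM structure of the default planted off-target panel
#: (1-3 mismatches, one DNA-bulge and one RNA-bulge site, NNG/NGN PAMs).
DEFAULT_OFFTARGET_SHAPES = (
    (1, None, "TGG"),
    (2, None, "AGG"),
    (2, None, "TAG"),
    (3, None, "CGT"),
    (3, ("DNA", 10), "GGG"),
    (1, None, "TCG"),
    (2, ("RNA", 8), "AGT"),
    (3, None, "TGA"),
)


def standard_scenario(
    seed: int,
    n_samples: int = 6,
    reads_per_sample: int = 200_000,
    genome_size: int = 120_000,
    n_contigs: int = 3,
    on_target_rate: float = 0.5,
    offtarget_rates: Sequence[float] = DEFAULT_OFFTARGET_RATES,
    locus_molecules: int = 5_000,
    translocation_rate: float = 0.01,
    donor: str | None = None,
    **overrides,
) -> SimTruth:
    """A ready-to-run simulated experiment mirroring the in vivo design.

    Builds a toy genome, plants one on-target site plus eight off-target
    sites (1-3 mismatches, one DNA-bulge and one RNA-bulge site) with tag
    integration rates spanning 0.5-10%, wires up the four-viewpoint library
    layout with the 46 bp dsODN as donor, and plants a translocation between
    the target site and the first off-target at 1% of edited molecules.
    """
    from .donors import iguide_duplex

    rng = np.random.default_rng(seed)
    descriptors = [SiteDescriptor(name="On", mismatches=0, pam="TGG",
                                  integration_rate=on_target_rate)]
    for i, (rate, (mm, bulge, pam)) in enumerate(
            zip(offtarget_rates, itertools.cycle(DEFAULT_OFFTARGET_SHAPES)),
            start=1):
        descriptors.append(SiteDescriptor(
            name=f"OT{i}", mismatches=mm, bulge=bulge, pam=pam,
            integration_rate=rate))
    # a pathologically self-similar random spacer can make a bulged
    # descriptor unplantable; redraw genome and spacer in that case
    for _ in range(5):
        genome = make_toy_genome(int(rng.integers(2 ** 31)),
                                 size=genome_size, contigs=n_contigs)
        spacer = rng.choice(_BASES, size=20).tobytes().decode()
        guide = GuideSpec(spacer=spacer)
        try:
            genome, sites = plant_sites(genome, guide, descriptors,
                                        seed=int(rng.integers(2 ** 31)))
            break
        except RuntimeError:
            continue
    else:
        raise RuntimeError("could not realise the site panel; try a new seed")
    donor = donor or iguide_duplex()[0].clean
    barcodes = make_barcodes(rng, n_samples)
    samples = {f"S{i + 1}": bc for i, bc in enumerate(barcodes)}
    layout = default_layout(donor, sites[0], genome)
    return SimTruth(
        seed=int(rng.integers(2 ** 31)),
        genome=genome, guide=guide, sites=sites, samples=samples,
        layout=layout, donor=donor,
        reads_per_sample=reads_per_sample,
        locus_molecules=locus_molecules,
        translocation_rates={"OT1": translocation_rate}
        if translocation_rate > 0 else {},
        **overrides,
    )


def write_sample_sheet(truth: SimTruth, path: str | Path,
                       treatment: dict[str, str] | None = None) -> None:
    """Sample sheet TSV: sample, barcode, condition label, subject id."""
    rows = []
    for i, (sample, barcode) in enumerate(truth.samples.items(), start=1):
        rows.append({
            "sample": sample,
            "barcode": barcode,
            "condition": (treatment or {}).get(sample, "treated"),
            "subject": f"mouse{i}",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
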