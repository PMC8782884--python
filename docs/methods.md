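# Methods

`guidetag` analyses sequencing libraries built by Tn5 tagmentation of
nuclease-treated genomic DNA, in which every molecule carries a unique
molecular identifier (UMI) and a sample barcode on the adapter side and is
amplified from one of four *viewpoints*: two locus-anchored primers
(`Locus_F`, `Locus_R`; UDiTaS-style readout of on-target editing outcomes)
and two primers anchored inside an integrated dsDNA tag (`Insert_F`,
`Insert_R`; GUIDE-seq-style genome-wide readout of double-strand-break
tagging). The package implements the full computational chain for both
readouts, plus a seeded synthetic-data generator so the entire pipeline is
testable without sequencing data.

## Preprocessing

Sample barcodes are matched allowing up to one mismatch; a read within one
mismatch of two barcodes is *discarded* as ambiguous rather than assigned
to the nearest, because downstream quantification is UMI counting and must
not be cross-contaminated. UMIs containing `N` are rejected. UMI and
barcode positions are configuration (`LibraryLayout`), defaulting to an
8 nt UMI followed by an 8 nt barcode at the start of the adapter-side read.

Viewpoint assignment and trimming use the expected read prefix — the
locus-specific primer for locus viewpoints, the residual tag end (default
16 nt of the dsODN) for insert viewpoints — requiring ≥ 90% ungapped
identity over the prefix. Insert-viewpoint reads lacking the tag are
mispriming products and are discarded before any integration-site calling.
The 90% ungapped rule is a deliberate simplification of dedicated
mispriming filters: it is transparent, testable, and sufficient at the
substitution error rates the generator models. Overlapping read pairs can
be merged (highest-quality base wins per position); the discovery chain
runs on the viewpoint-side read alone by default, which is the read that
carries the tag junction.

Read accounting is conservative by construction:
`assigned + ambiguous + unassigned + rejected = total`, checked by test.

## Alignment

The alignment *contract* — end-to-end alignments with coordinates, CIGAR
and edit distance — can be satisfied by ingesting SAM text from any
external aligner. The built-in engine exists so toy genomes need no
external binary: exact 13-mer seeding (k-mers occurring > 64 times are
masked) anchors candidate diagonals on both strands; each candidate window
is verified by unit-cost edit-distance DP (edlib), ties broken by leftmost
coordinate then + strand. Reads are unaligned when the best edit distance
exceeds 15% of the read length. On error-free 50 nt reads from a toy
genome recovery is 100%; at 1% substitution error ≥ 99% (tested).

Split (junction) alignment chains seeds per (reference, strand, diagonal)
over a combined index that names the genome contigs plus the donor and
vector sequences, picks the two best compatible chains, and places the
junction at the read offset minimising mismatches of prefix-vs-segment-1
plus suffix-vs-segment-2. Untemplated junction bases are allowed with an
affine-style cost (1 for the first base, 0.5 per additional), cheaper than
explaining them as mismatched extension — without this, short insertions
are systematically absorbed into whichever flank they partially match.
When junction microhomology makes the breakpoint ambiguous, the first
segment is maximised; consumers that care (the precise-junction check)
compensate by accepting any placement consistent with a blunt ligation.

## Off-target discovery

The discovery chain mirrors the tag-anchored readout: aligned insert-
viewpoint reads are clustered by their strand-aware 5′ start (single
linkage, gap ≤ 10 bp — both knobs are configuration standing in for the
upstream package defaults the source protocol delegates to), UMIs are
collapsed per peak and sample by exact string equality with a **≥ 3
supporting reads** floor that suppresses UMI singletons created by
sequencing errors, and each peak window (cluster span ± 25 bp) is searched
for a near-cognate protospacer.

The search accepts up to **6 mismatches** and at most **one bulge** —
either an extra genomic base (DNA bulge, inserted at an interior gap
1..L−1 of the spacer) or an unpaired spacer base (RNA bulge, interior
position 1..L−2) — and requires a G at PAM position 2 or 3 (the NNG/NGN
union) in the 3-mer 3′ of the site. The implementation evaluates all
placements on both strands with vectorised prefix/suffix mismatch counts;
tests prove it equal to explicit enumeration of every placement × bulge
configuration. The best match minimises (bulge count, mismatches), then
distance to the window centre, then leftmost start, then + strand. The
bulge-first objective means a bulged site that also admits a ≤ 6-mismatch
bulge-free reading is reported bulge-free; the generator accounts for this
when verifying planted sites.

Replicate filters act per site on per-sample counts: filter 1 (UMIs ≥ 5
and reads ≥ 50 in ≥ 4 of 6 samples) and filter 2 (UMIs ≥ 1 in ≥ 4 of 6).
Reported sites carry `umi_pct` per sample — the site's UMIs as a
percentage of all retained UMIs over reported sites in that sample (the
normalisation includes the on-target site; normalising to off-targets only
would be an equally defensible convention) — and are ranked by mean UMI
count, ties by coordinate. Evidence from `Insert_F` and `Insert_R` is
pooled per site; neither viewpoint is required on its own.

Prediction mode (`genome_scan`) is a separate, deliberately different
regime: exhaustive, mismatch-only (≤ 3 by default), NGG PAM — the
convention of in-silico off-target predictors against which discovery
results are compared with `overlap_sites` (same strand, starts within
10 bp).

## On-target outcome classification

Each retained UMI contributes one exemplar read (most frequent sequence,
ties by read id). Classification order: a second split segment on the
donor gives `donor_forward`/`donor_reverse` (orientation relative to the
genomic arm); on the vector, `vector_insertion`; on a distal locus
(different contig, opposite strand, or > 50 kb away), `translocation_candidate`.
Same-contig same-strand splits are deletions. Single-segment reads are
aligned to the locus window and classified by indel content in a ± 10 bp
window around the cut: any indel of total span < 50 bp is
`small_indel_sub`, ≥ 50 bp is `large_del_ins` (the boundary value 50 is
assigned to the large class so the mapping is total). Substitution-only
reads are edited only when more than one substituted base falls in the cut
window — a 1-base allowance that keeps isolated sequencing errors from
inflating edit rates; substitutions outside the window are ignored.
Class fractions are over classified UMIs and sum to 1.

The cut site convention is a blunt cut 3 bp 5′ of the PAM on the
protospacer strand (standard SpyCas9 biochemistry). A donor junction is
*precise* when the genomic arm ends exactly at that cut, the donor begins
at its terminal base, and no untemplated bases intervene — evaluated up to
the junction-placement ambiguity introduced by arm/donor microhomology.
Junctions are annotated with the deletion length between breakpoints,
inserted bases, and the longest identical flank shared by the two sides
(microhomology, reported with its side and sequence; symmetric under
reverse complement, tested).

A minimal amplicon indel quantifier serves validation-style inputs: the
percentage of aligned reads with ≥ 1 inserted or deleted base within
cut ± 10 bp; substitutions never count; results from < 100 aligned reads
are flagged low-coverage.

## Translocations and statistics

Translocation candidates whose distal segment falls within 25 bp of a
known site are aggregated per (partner site, arm combination); arms are
named L/R by reference orientation relative to each cut. Partners matching
no known site are kept as a separate novel-partner list. Rates use edited
(non-wild-type) UMIs at the viewpoint as the denominator. `predicted_junction`
reconstructs the reference sequence of a precise blunt ligation between
two cuts for annotating observed junction deletions.

Rates are arcsine-square-root transformed (arcsin √p, variance-stabilising
for proportions) before testing. Two-group designs use Welch's t
(unequal variances, Welch–Satterthwaite df, two-sided); designs with more
than two groups use one-way ANOVA with pre-specified pairwise contrasts on
the pooled error term. P-values are BH-adjusted per experiment across the
*observed* events — pairs with no junction UMIs anywhere never become
events and so are outside the family. Without control samples a
one-sample test against zero is refused (flagged untestable), not
improvised. Degenerate inputs: identical groups give t = 0, p = 1; two
zero-variance groups with different means are untestable. Correlations
report Pearson r (p from t = r√((n−2)/(1−r²)) on n−2 df) and Spearman ρ.
Note the BH step-up transform is not idempotent; the tested guarantees are
monotonicity in sorted-p order, order preservation, adjusted ≥ raw, and
exact agreement with the textbook formula.

## Synthetic data generator

The generator emulates the four-viewpoint experiment with everything the
pipeline must see — and defines the conditions the tests run under:

- **Genome**: uniform random DNA (default 120 kb over 3 contigs). Real
  genomes have repeats, GC structure and homology the toy genome lacks, so
  passing tests demonstrate algorithmic correctness, not mapping
  performance on mm10-scale references (an external aligner's SAM can be
  ingested for that).
- **Site panel**: one on-target site plus eight off-targets with 1–3
  mismatches, one DNA-bulge and one RNA-bulge site, NNG/NGN PAMs, and tag
  integration rates spanning 0.5–10% per molecule — the regime the
  replicate filters are designed around. Each planted site is verified by
  running the discovery search on its window; the descriptor must be
  reproduced exactly, otherwise placement is retried (bulge position
  re-drawn if needed, since self-similar spacers can make some bulge
  placements unrealisable).
- **Insert libraries**: per sample, a molecule budget derived from the
  read-depth target and the mean PCR duplication; each site receives
  Binomial(budget, rate) tagged molecules split between the two insert
  viewpoints, plus 2% mispriming molecules lacking the tag.
- **Locus libraries**: a per-molecule editing-class draw (default 55%
  wild type, 25% donor forward, 15% small indel, 5% large deletion of
  60–1500 bp), with 1% of edited molecules converted to translocations to
  the first off-target in treated samples and none in designated controls.
- **Noise**: PCR duplication from a truncated geometric distribution
  (p = 0.35, cap 12; mean ≈ 2.9) so a realistic fraction of UMIs falls
  below the 3-read floor and the collapse rule is actually exercised;
  substitution-only sequencing error at 0.2% per base (keeps all truth
  oracles closed-form; indel errors are out of scope); 0.1% of reads get
  an `N` in the UMI. 8 nt UMIs imply a small birthday-collision rate at
  the deepest sites (≈ 1–2% of molecules), which biases absolute UMI
  counts slightly downward but not rates or rankings.
- **Determinism**: all randomness flows from one seeded generator;
  identical (seed, configuration) gives byte-identical FASTQ.

## Problem sizes

The full-scale discovery check runs 6 samples × 200,000 reads each
(~1.2 M read pairs) through the complete chain in a few minutes on one
core; the shared fixture for the other pipeline tests uses 6 × 12,000
reads and 2,500 locus molecules per sample, and `scripts/acceptance.py`
defaults to 6 × 60,000 reads — sizes chosen so every planted feature is
comfortably above its filter threshold while a full run stays fast. The
search-equivalence check uses 100 random guide/window pairs with window
lengths log-uniform between 50 bp and 5 kb; genome-scan equivalence uses
50 random guides on 10 kb genomes. Translocation detection power is
measured over 100 seeded count-level replicates with 2,000 edited UMIs
per sample (a deep UDiTaS library), 3 treated vs 3 control.

## Known limitations

- Exact-match UMI collapse (no error-aware clustering); the 3-read floor
  is the only defence against UMI errors, matching the documented rule.
- The built-in aligner is for toy genomes; it makes no attempt to match a
  production aligner's mapping-quality model or repeat resolution.
- Split alignment resolves at most two segments; complex multi-junction
  alleles fall into `unexplained`.
- The locus simulator writes the `Locus_F` viewpoint only; `Locus_R`
  analysis uses the same code path but has no generator counterpart.
- Substitution-only error is a modelling choice, not a claim about
  sequencers; indel sequencing errors would require a tolerance in the
  precise-junction and small-indel boundaries.
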