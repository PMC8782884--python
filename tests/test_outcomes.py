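import pytest

from oracles import binom_ci

from guidetag.align import KmerIndex, split_align
from guidetag.outcomes import (DONOR_REF, VECTOR_REF, EditClass, LocusSpec,
                               blunt_cut, classify_exemplar,
                               detect_breakpoints, microhomology,
                               precise_junction_check, quantify_amplicon_indels,
                               tabulate_outcomes)
from guidetag.seqio import GenomicInterval, revcomp
from guidetag.simdata import simulate_locus_library, standard_scenario

DONOR = "GCTCGCGTTTAATTGAGTTGTCATATGTTAATAACGGTATACGCGA"
VECTOR = ("ATGGTGAGCAAGGGCGAGGAGCTGTTCACCGGGGTGGTGCCCATCCTGGTCGAGCTGGACG"
          "GCGACGTAAACGGCCACAAGTTCAGCGTGTCCGGCGAGGGCGAGGGCGATGCCACCTACGG")


@pytest.fixture(scope="module")
def locus_setup(toy_genome):
    contig = "chrS1"
    cut = 5_000
    index = KmerIndex.from_genome(toy_genome,
                                  extra={DONOR_REF: DONOR, VECTOR_REF: VECTOR})
    locus = LocusSpec(contig=contig,
                      window=GenomicInterval(contig, cut - 800, cut + 800),
                      cut_site=cut)
    return toy_genome, index, locus


def _read(genome, cut, left=45, payload=100):
    """Reference read spanning the cut: arm end at the cut site."""
    ref = genome["chrS1"]
    return ref[cut - left:cut - left + payload], ref


class TestBluntCut:
    def test_plus_strand_three_from_pam(self):
        assert blunt_cut(100, 120, "+") == 117

    def test_minus_strand_mirrored(self):
        assert blunt_cut(100, 120, "-") == 103


class TestClassifyExemplar:
    def test_reference_read_is_wild_type(self, locus_setup):
        genome, index, locus = locus_setup
        read, _ = _read(genome, locus.cut_site)
        assert classify_exemplar(read, index, locus).edit_class \
            is EditClass.wild_type

    def test_small_deletion_at_cut(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        cut = locus.cut_site
        read = ref[cut - 45:cut] + ref[cut + 3:cut + 58]
        res = classify_exemplar(read, index, locus)
        assert res.edit_class is EditClass.small_indel_sub

    def test_large_deletion(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        cut = locus.cut_site
        read = ref[cut - 45:cut] + ref[cut + 120:cut + 175]
        res = classify_exemplar(read, index, locus)
        assert res.edit_class is EditClass.large_del_ins
        assert res.junction.deletion_length == 120

    def test_exactly_fifty_bp_deletion_is_large(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        cut = locus.cut_site
        read = ref[cut - 45:cut] + ref[cut + 50:cut + 105]
        res = classify_exemplar(read, index, locus)
        assert res.edit_class is EditClass.large_del_ins

    def test_donor_forward_and_reverse(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        cut = locus.cut_site
        fwd = ref[cut - 45:cut] + DONOR[:45]
        rev = ref[cut - 45:cut] + revcomp(DONOR)[:45]
        assert classify_exemplar(fwd, index, locus).edit_class \
            is EditClass.donor_forward
        assert classify_exemplar(rev, index, locus).edit_class \
            is EditClass.donor_reverse

    def test_vector_insertion(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        cut = locus.cut_site
        read = ref[cut - 45:cut] + VECTOR[:45]
        assert classify_exemplar(read, index, locus).edit_class \
            is EditClass.vector_insertion

    def test_distal_partner_is_translocation_candidate(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        cut = locus.cut_site
        read = ref[cut - 45:cut] + genome["chrS2"][7_000:7_045]
        res = classify_exemplar(read, index, locus)
        assert res.edit_class is EditClass.translocation_candidate
        assert res.partner[0] == "chrS2"
        assert abs(res.partner[1] - 7_000) <= 5

    def test_substitution_only_within_allowance_is_wild_type(self,
                                                             locus_setup):
        genome, index, locus = locus_setup
        read, _ = _read(genome, locus.cut_site)
        i = 45  # the cut position within the read
        flipped = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        one_sub = read[:i] + flipped + read[i + 1:]
        assert classify_exemplar(one_sub, index, locus).edit_class \
            is EditClass.wild_type

    def test_clustered_substitutions_called_edited(self, locus_setup):
        genome, index, locus = locus_setup
        read, _ = _read(genome, locus.cut_site)
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}
        edited = list(read)
        for i in (43, 45, 47):
            edited[i] = sub[edited[i]]
        assert classify_exemplar("".join(edited), index, locus).edit_class \
            is EditClass.small_indel_sub


class TestBreakpoints:
    def _split(self, index, read):
        return split_align(read, index)

    def test_deletion_length_from_gap(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        read = ref[3_000:3_030] + ref[3_150:3_180]
        j = detect_breakpoints(self._split(index, read))
        assert (j.left_break, j.right_break) == (3_030, 3_150)
        assert j.deletion_length == 120

    def test_abutting_segments_deletion_zero(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        read = ref[3_000:3_060]
        res = self._split(index, read)
        j = detect_breakpoints(res)
        assert j.deletion_length == 0

    def test_junction_insertion_reported(self, locus_setup):
        genome, index, locus = locus_setup
        ref = genome["chrS1"]
        read = ref[3_000:3_030] + "AGTC" + ref[3_150:3_180]
        j = detect_breakpoints(self._split(index, read))
        assert j.inserted_bases == "AGTC"


class TestMicrohomology:
    def test_constructed_four_base_homology(self):
        refseq = "AAAACCTGGA" + "GGGGG" + "CTTGGA" + "TTTTT"
        # breaks chosen so both flanks end in TGGA
        left, right = 10, 21
        k, seq, _ = microhomology(refseq, left, right)
        assert (k, seq) == (4, "TGGA")

    def test_no_shared_bases(self):
        k, seq, _ = microhomology("AAAACCCC", 2, 6)
        assert k == 0 and seq == ""

    def test_full_flank_identity(self):
        refseq = "GATTACCAGT" + "GATTACCAGT"
        k, seq, _ = microhomology(refseq, 10, 20)
        assert k == 10

    def test_symmetric_under_revcomp(self, rng):
        for _ in range(20):
            refseq = "".join(rng.choice(list("ACGT"), size=60))
            left = int(rng.integers(10, 25))
            right = int(rng.integers(35, 50))
            k1, _, _ = microhomology(refseq, left, right)
            n = len(refseq)
            k2, _, _ = microhomology(revcomp(refseq), n - right, n - left)
            assert k1 == k2


class TestPreciseJunction:
    def _donor_split(self, index, genome, cut, lead="", arm_trim=0):
        ref = genome["chrS1"]
        read = ref[cut - 45:cut - arm_trim] + lead + DONOR[:45]
        return split_align(read, index)

    def test_perfect_junction_precise(self, locus_setup):
        genome, index, locus = locus_setup
        res = self._donor_split(index, genome, locus.cut_site)
        assert precise_junction_check(res, len(DONOR), locus.cut_site)

    def test_resected_arm_imprecise(self, locus_setup):
        genome, index, locus = locus_setup
        res = self._donor_split(index, genome, locus.cut_site, arm_trim=2)
        assert not precise_junction_check(res, len(DONOR), locus.cut_site)

    def test_inserted_base_imprecise(self, locus_setup):
        genome, index, locus = locus_setup
        res = self._donor_split(index, genome, locus.cut_site, lead="T")
        assert not precise_junction_check(res, len(DONOR), locus.cut_site)


class TestTabulate:
    def test_fraction_arithmetic(self):
        classes = ([EditClass.wild_type] * 50
                   + [EditClass.donor_forward] * 30
                   + [EditClass.small_indel_sub] * 20)
        table = tabulate_outcomes(classes, sample="S1")
        fr = table.fractions
        assert fr[EditClass.wild_type] == pytest.approx(0.5)
        assert fr[EditClass.donor_forward] == pytest.approx(0.3)
        assert fr[EditClass.small_indel_sub] == pytest.approx(0.2)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_single_class(self):
        table = tabulate_outcomes([EditClass.wild_type] * 5)
        assert table.fractions[EditClass.wild_type] == 1.0

    def test_empty_reports_undefined(self):
        assert tabulate_outcomes([]).fractions is None


class TestAmpliconIndels:
    AMPLICON = None

    @pytest.fixture
    def amplicon(self, toy_genome):
        return toy_genome["chrS2"][1_000:1_240]

    def test_ten_percent_deletions(self, amplicon):
        cut = 120
        wt = amplicon[20:220]
        dele = amplicon[20:115] + amplicon[118:223]
        reads = [wt] * 90 + [dele] * 10
        res = quantify_amplicon_indels(reads, amplicon, cut)
        assert res.indel_pct == pytest.approx(10.0)
        assert not res.low_coverage

    def test_substitutions_do_not_count(self, amplicon):
        cut = 120
        wt = amplicon[20:220]
        sub = wt[:100] + {"A": "C", "C": "A", "G": "T",
                          "T": "G"}[wt[100]] + wt[101:]
        res = quantify_amplicon_indels([wt] * 60 + [sub] * 60, amplicon, cut)
        assert res.indel_pct == 0.0

    def test_low_coverage_flag(self, amplicon):
        res = quantify_amplicon_indels([amplicon[20:220]] * 10, amplicon, 120)
        assert res.low_coverage

    def test_planted_rate_within_binomial_ci(self, amplicon, rng):
        cut = 120
        wt = amplicon[20:220]
        dele = amplicon[20:117] + amplicon[121:224]
        n = 1_000
        edited = rng.random(n) < 0.05
        reads = [dele if e else wt for e in edited]
        res = quantify_amplicon_indels(reads, amplicon, cut)
        lo, hi = binom_ci(0.05, n, alpha=0.01)
        assert lo * 100 <= res.indel_pct <= hi * 100


class TestSimulatedMixtureRecovery:
    def test_class_fractions_track_truth(self):
        """Estimated outcome fractions stay inside exact binomial 99% CIs."""
        truth = standard_scenario(seed=31, n_samples=1, genome_size=40_000,
                                  locus_molecules=1_500,
                                  translocation_rate=0.0)
        pairs, truth_table = simulate_locus_library(truth)
        from guidetag.pipeline import run_outcomes
        on = truth.on_target
        locus = LocusSpec(
            contig=on.contig,
            window=GenomicInterval(on.contig, on.cut_site - 2_000,
                                   min(on.cut_site + 2_000,
                                       truth.genome.lengths[on.contig])),
            cut_site=on.cut_site)
        res = run_outcomes(pairs, truth.genome, locus, truth.layout,
                           truth.samples, donor=truth.donor)
        table = res.tables["S1"]
        fr = table.fractions
        assert sum(fr.values()) == pytest.approx(1.0)
        for cls, planted in truth.locus_mix.items():
            lo, hi = binom_ci(planted, table.total, alpha=0.01)
            assert lo <= fr[cls] <= hi, (cls, fr[cls], (lo, hi))
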