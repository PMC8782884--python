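import numpy as np
import pandas as pd
import pytest

from oracles import best_protospacer, rc

from guidetag.discovery import (FILTER1, FILTER2, GuideSpec,
                                TagAlignment, apply_replicate_filter,
                                call_peaks, collapse_umis, genome_scan,
                                overlap_sites, rank_and_report,
                                search_protospacer)
from guidetag.simdata import make_toy_genome


def _embed(rng, site, pam, length=160):
    """Random window with site+pam planted at a random offset."""
    w = rng.choice(list("ACGT"), size=length)
    full = site + pam
    pos = int(rng.integers(20, length - len(full) - 20))
    w[pos:pos + len(full)] = list(full)
    return "".join(w), pos


class TestCollapseUmis:
    def test_read_count_floor(self):
        reads = ([("A", f"rA{i}", "x") for i in range(5)]
                 + [("B", f"rB{i}", "x") for i in range(2)]
                 + [("C", f"rC{i}", "x") for i in range(3)])
        retained = collapse_umis(reads, min_reads=3)
        assert set(retained) == {"A", "C"}
        assert retained["A"].read_count == 5

    def test_empty_input(self):
        assert collapse_umis([]) == {}

    def test_all_singletons_dropped(self):
        reads = [(f"U{i}", f"r{i}", "x") for i in range(10)]
        assert collapse_umis(reads, min_reads=3) == {}

    def test_exemplar_is_most_frequent_sequence(self):
        reads = [("A", "r1", "AAAA"), ("A", "r2", "CCCC"),
                 ("A", "r3", "CCCC"), ("A", "r4", "AAAA"),
                 ("A", "r0", "CCCC")]
        ex = collapse_umis(reads, min_reads=3)["A"]
        assert ex.sequence == "CCCC"
        assert ex.read_id == "r0"  # tie on sequence count broken by read id


class TestCallPeaks:
    def _aln(self, pos, contig="chr1", sample="S1"):
        return TagAlignment(sample=sample, viewpoint="Insert_F", umi="A" * 8,
                            read_id=f"r{pos}", contig=contig, pos5=pos,
                            strand="+")

    def test_nearby_starts_form_one_peak(self):
        peaks = call_peaks([self._aln(p) for p in (1000, 1003, 1007)],
                           cluster_gap=10)
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (1000, 1008)

    def test_distant_starts_split(self):
        peaks = call_peaks([self._aln(1000), self._aln(5000)], cluster_gap=10)
        assert len(peaks) == 2

    def test_empty_input(self):
        assert call_peaks([]) == []

    def test_summit_is_modal_start(self):
        alns = [self._aln(p) for p in (100, 104, 104, 104, 109)]
        assert call_peaks(alns)[0].summit == 104


class TestSearchProtospacer:
    SPACER = "GACGCATAAAGATGAGACGC"

    @pytest.fixture
    def g(self):
        return GuideSpec(spacer=self.SPACER)

    def test_exact_site_with_nng_pam(self, g, rng):
        window, pos = _embed(rng, self.SPACER, "TGG")
        hit = search_protospacer(window, g)
        assert hit.mismatches == 0 and hit.bulge is None
        assert (hit.start, hit.strand) == (pos, "+")

    def test_three_mismatches_ngn_pam(self, g, rng):
        site = "TTCGCATAAAGATGAGACGA"  # 3 substitutions
        window, pos = _embed(rng, site, "AGT")
        hit = search_protospacer(window, g)
        assert hit.mismatches == 3 and hit.start == pos

    def test_seven_mismatches_rejected(self, g, rng):
        site = "TTTTTTTAAAGATGAGACGC"  # 7 substitutions in a row
        window, _ = _embed(rng, site, "TGG", length=80)
        hit = search_protospacer(window, g)
        assert hit is None or hit.mismatches <= 6

    def test_dna_bulge_with_one_mismatch(self, g, rng):
        # extra genomic base at gap 10, one substitution at position 2
        site = self.SPACER[:10] + "T" + self.SPACER[10:]
        site = site[:2] + "T" + site[3:]
        window, pos = _embed(rng, site, "CGG")
        hit = search_protospacer(window, g)
        assert hit.bulge is not None and hit.bulge[0] == "DNA"
        assert hit.mismatches == 1 and hit.start == pos

    def test_pam_without_g2_or_g3_rejected(self, g, rng):
        window, _ = _embed(rng, self.SPACER, "ATT", length=80)
        hit = search_protospacer(window, g)
        # the planted placement must not be returned with the bad PAM
        assert hit is None or hit.mismatches > 0

    def test_minus_strand_coordinates(self, g, rng):
        window, pos = _embed(rng, self.SPACER, "TGG")
        flipped = rc(window)
        hit = search_protospacer(flipped, g)
        assert hit.strand == "-"
        assert hit.start == len(window) - (pos + len(self.SPACER))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle(self, seed):
        """DP search equals brute-force enumeration on random windows."""
        rng = np.random.default_rng(1000 + seed)
        spacer = "".join(rng.choice(list("ACGT"), size=20))
        guide = GuideSpec(spacer=spacer)
        length = int(rng.integers(40, 300))
        window = "".join(rng.choice(list("ACGT"), size=length))
        hit = search_protospacer(window, guide)
        expected = best_protospacer(window, guide)
        if expected is None:
            assert hit is None
        else:
            bulges, mism, start, end, strand, _ = expected
            assert hit is not None
            assert (hit.bulge_count, hit.mismatches, hit.start, hit.end,
                    hit.strand) == (bulges, mism, start, end, strand)


def _site_df(rows):
    base = {"contig": "chr1", "start": 100, "end": 120, "strand": "+",
            "site_seq": "A" * 20, "mismatches": 1, "bulge": "none",
            "pam": "TGG"}
    out = []
    for i, counts in enumerate(rows):
        row = dict(base, start=100 + 1000 * i, end=120 + 1000 * i)
        for j, (u, r) in enumerate(counts, start=1):
            row[f"umi_S{j}"] = u
            row[f"reads_S{j}"] = r
        out.append(row)
    return pd.DataFrame(out)


class TestReplicateFilter:
    def test_filter1_example_retained(self):
        df = _site_df([[(6, 60), (5, 55), (7, 80), (5, 52), (0, 0), (1, 9)]])
        assert len(apply_replicate_filter(df, FILTER1)) == 1

    def test_filter2_keeps_what_filter1_drops(self):
        df = _site_df([[(1, 10), (1, 8), (1, 12), (1, 9), (0, 0), (0, 0)]])
        assert len(apply_replicate_filter(df, FILTER1)) == 0
        assert len(apply_replicate_filter(df, FILTER2)) == 1

    def test_three_of_six_removed_under_both(self):
        df = _site_df([[(9, 90), (9, 90), (9, 90), (0, 0), (0, 0), (0, 0)]])
        assert apply_replicate_filter(df, FILTER1).empty
        assert apply_replicate_filter(df, FILTER2).empty

    def test_filters_are_monotone(self, rng):
        """Every site passing the strict filter passes the relaxed one."""
        rows = [[(int(rng.integers(0, 10)), int(rng.integers(0, 100)))
                 for _ in range(6)] for _ in range(40)]
        df = _site_df(rows)
        strict = apply_replicate_filter(df, FILTER1)
        relaxed = apply_replicate_filter(df, FILTER2)
        assert set(strict.index) <= set(relaxed.index)

    def test_missing_sample_column_is_error(self):
        df = _site_df([[(1, 1)] * 6]).drop(columns=["reads_S3"])
        with pytest.raises(KeyError):
            apply_replicate_filter(df, FILTER1)


class TestRankAndReport:
    def test_umi_pct_normalisation(self):
        df = _site_df([[(90, 900)] * 6, [(10, 100)] * 6])
        out = rank_and_report(df)
        assert list(out["umi_pct_S1"]) == [90.0, 10.0]
        assert list(out["rank"]) == [1, 2]

    def test_single_site_pct_100(self):
        out = rank_and_report(_site_df([[(7, 70)] * 6]))
        assert out.loc[0, "umi_pct_S2"] == 100.0

    def test_pct_sums_to_100_per_sample(self, rng):
        rows = [[(int(rng.integers(1, 50)), 100)] * 6 for _ in range(10)]
        out = rank_and_report(_site_df(rows))
        for s in range(1, 7):
            assert out[f"umi_pct_S{s}"].sum() == pytest.approx(100.0)

    def test_equal_means_tie_broken_by_coordinate(self):
        df = _site_df([[(5, 50)] * 6, [(5, 50)] * 6])
        out = rank_and_report(df)
        assert out.loc[0, "start"] < out.loc[1, "start"]


class TestGenomeScan:
    def test_planted_sites_by_mismatch_budget(self, rng):
        genome = make_toy_genome(seed=21, size=10_000, contigs=1)
        spacer = "".join(rng.choice(list("ACGT"), size=20))
        guide = GuideSpec(spacer=spacer)
        seqs = {}
        contig = genome["chrS1"]
        exact = spacer + "TGG"
        three = "TTT" + spacer[3:] + "AGG"
        four = "TTTT" + spacer[4:] + "CGG"
        edited = (contig[:1000] + exact + contig[1050:3000] + three
                  + contig[3050:5000] + four + contig[5050:])
        from guidetag.seqio import GenomeRef
        g = GenomeRef({"chrS1": edited})
        hits = genome_scan(guide, g, max_mismatches=3)
        found_mm = set(hits["mismatches"])
        assert 0 in found_mm and 3 in found_mm
        assert (hits["mismatches"] <= 3).all()

    def test_agrees_with_bruteforce(self, rng):
        """Vectorised scan equals direct per-position enumeration."""
        genome = make_toy_genome(seed=22, size=10_000, contigs=1)
        seq = genome["chrS1"]
        for trial in range(5):
            spacer = "".join(rng.choice(list("ACGT"), size=20))
            guide = GuideSpec(spacer=spacer)
            hits = genome_scan(guide, genome, max_mismatches=3)
            brute = []
            for strand, s in (("+", seq), ("-", rc(seq))):
                for i in range(len(s) - 23 + 1):
                    mism = sum(a != b for a, b in zip(s[i:i + 20], spacer))
                    if mism <= 3 and s[i + 22] == "G":  # NGG needs G at 2&3
                        if s[i + 21] == "G":
                            start = i if strand == "+" else len(s) - i - 20
                            brute.append((start, strand, mism))
            got = sorted(zip(hits["start"], hits["strand"],
                             hits["mismatches"]))
            assert got == sorted(brute)


class TestOverlapSites:
    def _df(self, rows):
        return pd.DataFrame([{"contig": c, "start": s, "end": s + 20,
                              "strand": st} for c, s, st in rows])

    def test_identical_sites_intersect(self):
        a = self._df([("chr1", 100, "+")])
        b = self._df([("chr1", 100, "+")])
        parts = overlap_sites(a, b)
        assert len(parts["shared_a"]) == 1 and parts["a_only"].empty

    def test_within_tolerance_paired(self):
        a = self._df([("chr1", 100, "+")])
        b = self._df([("chr1", 105, "+")])
        assert len(overlap_sites(a, b, tolerance_bp=10)["shared_a"]) == 1

    def test_disjoint_contigs_exclusive(self):
        a = self._df([("chr1", 100, "+")])
        b = self._df([("chr2", 100, "+")])
        parts = overlap_sites(a, b)
        assert parts["shared_a"].empty
        assert len(parts["a_only"]) == 1 and len(parts["b_only"]) == 1
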