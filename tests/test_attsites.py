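import numpy as np
import pytest

from proviscope.attsites import (
    DifConsensus,
    IUPAC_SETS,
    build_logo,
    find_direct_repeats,
    find_internal_dif,
    iupac_match_count,
    scan_dif,
)
from proviscope.genome_io import Contig, Interval, ProviscopeError, reverse_complement

from conftest import random_dna
from oracles import dif_scan_naive, direct_repeats_naive

CONS = DifConsensus.default()


class TestConsensus:
    def test_default_partition(self):
        assert len(CONS) == 28
        assert CONS.left_arm == (1, 11)
        assert CONS.spacer == (12, 17)
        assert CONS.right_arm == (18, 28)

    def test_non_tiling_rejected(self):
        with pytest.raises(ProviscopeError, match="tile"):
            DifConsensus("A" * 28, (1, 11), (13, 17), (18, 28))

    def test_reverse_complement_round_trip(self):
        rc = CONS.reverse_complement()
        assert rc.iupac == reverse_complement(CONS.iupac)
        assert rc.reverse_complement().iupac == CONS.iupac


class TestIupacMatchCount:
    def test_self_match_saturates(self):
        score = iupac_match_count(CONS.iupac, CONS)
        assert score.total_matches == 28
        assert score.left_arm_matches == 11
        assert score.spacer_matches == 6
        assert score.right_arm_matches == 11

    def test_complement_of_a_only_consensus(self):
        cons = DifConsensus("A" * 28, (1, 11), (12, 17), (18, 28))
        assert iupac_match_count("T" * 28, cons).total_matches == 0

    def test_n_never_matches(self):
        cons = DifConsensus("N" * 28, (1, 11), (12, 17), (18, 28))
        assert iupac_match_count("N" * 28, cons).total_matches == 0
        assert iupac_match_count("A" * 28, cons).total_matches == 28

    def test_length_mismatch(self):
        with pytest.raises(ProviscopeError, match="length mismatch"):
            iupac_match_count("ACGT", CONS)

    def test_mean_matches_analytic_expectation(self, rng):
        n = 10_000
        exp = sum(len(IUPAC_SETS[c]) / 4 for c in CONS.iupac)
        var = sum((len(IUPAC_SETS[c]) / 4) * (1 - len(IUPAC_SETS[c]) / 4)
                  for c in CONS.iupac)
        totals = [iupac_match_count(random_dna(rng, 28), CONS).total_matches
                  for _ in range(n)]
        se = np.sqrt(var / n)
        assert abs(np.mean(totals) - exp) <= 3 * se

    def test_reverse_complement_invariance(self, rng):
        rc_cons = CONS.reverse_complement()
        for _ in range(50):
            s = random_dna(rng, 28)
            a = iupac_match_count(s, CONS).total_matches
            b = iupac_match_count(reverse_complement(s), rc_cons).total_matches
            assert a == b


class TestScanDif:
    def test_planted_exact_site_found(self, rng):
        inst = "".join(IUPAC_SETS[c][0] for c in CONS.iupac)
        seq = random_dna(rng, 2000) + inst + random_dna(rng, 2000)
        sites = scan_dif(Contig("c", seq), CONS, min_total=28)
        assert [(s.interval.start, s.strand) for s in sites] == [(2001, "+")]

    def test_reverse_strand_plant_mirrored(self, rng):
        inst = "".join(IUPAC_SETS[c][0] for c in CONS.iupac)
        seq = random_dna(rng, 1000) + reverse_complement(inst) + random_dna(rng, 1000)
        sites = scan_dif(Contig("c", seq), CONS, min_total=28)
        assert [(s.interval.start, s.interval.end, s.strand)
                for s in sites] == [(1001, 1028, "-")]

    @pytest.mark.parametrize("seed", range(12))
    def test_against_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 3000)
        got = {}
        for s in scan_dif(seq, CONS, min_total=16, min_best_arm=6):
            got[(s.interval.start, s.strand)] = s.score.total_matches
        naive = dif_scan_naive(seq, CONS, 16, 6, IUPAC_SETS)
        # the scanner resolves same-strand overlaps to the best site, so
        # every reported site must be in the naive set with equal score,
        # and every naive site must overlap a reported one at >= score
        for k, v in got.items():
            assert naive[k] == v
        for (start, strand), total in naive.items():
            cover = [v for (s2, st2), v in got.items()
                     if st2 == strand and abs(s2 - start) < 28]
            assert cover and max(cover) >= total


class TestDirectRepeats:
    def test_planted_identical_13mer(self, rng):
        core = random_dna(rng, 13)
        left = random_dna(rng, 120) + core + random_dna(rng, 30)
        right = random_dna(rng, 40) + core + random_dna(rng, 110)
        pairs = find_direct_repeats(left, right, min_len=13, max_mismatch=0)
        assert pairs
        top = pairs[0]
        assert top.repeat_length >= 13 and top.mismatches == 0
        assert left[top.attL.start - 1 : top.attL.end] == \
               right[top.attR.start - 1 : top.attR.end]

    def test_disjoint_windows_empty(self):
        assert find_direct_repeats("A" * 50, "C" * 50, min_len=8) == []

    def test_min_len_floor(self):
        with pytest.raises(ProviscopeError):
            find_direct_repeats("ACGTACGTACGT", "ACGTACGTACGT", min_len=4)

    def test_window_swap_symmetry(self, rng):
        left = random_dna(rng, 150)
        right = random_dna(rng, 150)
        fwd = {(p.attL.start, p.attR.start, p.repeat_length, p.mismatches)
               for p in find_direct_repeats(left, right, 8, 1)}
        rev = {(p.attR.start, p.attL.start, p.repeat_length, p.mismatches)
               for p in find_direct_repeats(right, left, 8, 1)}
        assert fwd == rev

    @pytest.mark.parametrize("seed", range(15))
    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_against_quadratic_oracle(self, seed, max_mismatch):
        rng = np.random.default_rng(seed)
        left = random_dna(rng, 150)
        right = random_dna(rng, 150)
        got = {(p.attL.start, p.attR.start, p.repeat_length, p.mismatches)
               for p in find_direct_repeats(left, right, 8, max_mismatch)}
        assert got == direct_repeats_naive(left, right, 8, max_mismatch)


class TestInternalDif:
    def test_no_planted_site_empty(self, rng):
        seq = random_dna(rng, 6000)
        contig = Contig("c", seq)
        sites = find_internal_dif(contig, Interval(500, 5500), CONS,
                                  min_total=24)
        assert sites == []

    def test_planted_interior_site_with_terminus_distance(self, rng):
        inst = "".join(IUPAC_SETS[c][0] for c in CONS.iupac)
        # place the site so its end is exactly 200 bp from the right
        # terminus of the provirus extent
        left = random_dna(rng, 4000)
        seq = left + inst + random_dna(rng, 200) + random_dna(rng, 1000)
        contig = Contig("c", seq)
        extent = Interval(1000, 4000 + 28 + 200)
        sites = find_internal_dif(contig, extent, CONS, min_total=26)
        assert len(sites) == 1
        site, dist = sites[0]
        assert site.interval.start == 4001
        assert dist == 200

    def test_equals_scan_dif_on_extracted_interior(self, rng):
        seq = random_dna(rng, 5000)
        contig = Contig("c", seq)
        extent = Interval(200, 4800)
        lo, hi = 200 + 28, 4800 - 28
        inner = scan_dif(seq[lo - 1 : hi], CONS, min_total=17, offset=lo - 1)
        got = find_internal_dif(contig, extent, CONS, min_total=17)
        assert [(s.interval.start, s.strand) for s, _ in got] == \
               sorted([(s.interval.start, s.strand) for s in inner])


class TestBuildLogo:
    def test_pure_column_two_bits(self):
        df = build_logo(["A", "A", "A", "A"], correction=False)
        assert df.loc[0, "bits"] == pytest.approx(2.0)
        assert df.loc[0, "A"] == pytest.approx(2.0)

    def test_uniform_column_zero_bits(self):
        df = build_logo(["A", "C", "G", "T"], correction=False)
        assert df.loc[0, "bits"] == pytest.approx(0.0)

    def test_three_to_one_column(self):
        df = build_logo(["AA", "AA", "AA", "CA"], correction=False)
        expect = 2 - (0.75 * np.log2(4 / 3) + 0.25 * np.log2(4))
        assert df.loc[0, "bits"] == pytest.approx(expect, abs=1e-4)
        assert expect == pytest.approx(1.1887, abs=1e-4)

    def test_small_sample_correction_reduces_bits(self):
        on = build_logo(["A"] * 4, correction=True)
        off = build_logo(["A"] * 4, correction=False)
        assert on.loc[0, "bits"] == pytest.approx(
            2.0 - 3 / (2 * np.log(2) * 4))
        assert on.loc[0, "bits"] < off.loc[0, "bits"]

    def test_errors(self):
        with pytest.raises(ProviscopeError, match="at least 2"):
            build_logo(["ACGT"])
        with pytest.raises(ProviscopeError, match="ragged"):
            build_logo(["ACGT", "ACG"])
        with pytest.raises(ProviscopeError, match="alphabet"):
            build_logo(["ACGN", "ACGT"])
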