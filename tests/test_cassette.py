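import numpy as np
import pytest

from proviscope.cassette import (
    CassetteRules,
    assemble_cassette,
    coiled_coil_prob,
    hydropathy_tm,
    kyte_doolittle_scale,
    parse_pattern,
    pilot_evidence,
    scan_rcr_motifs,
)
from proviscope.genome_io import ProviscopeError, find_orfs
from proviscope.homology import scan_for_anchors
from proviscope import synthetic

from conftest import AA20, random_protein
from oracles import scan_motifs_naive


class TestMotifPatterns:
    def test_parse_pattern(self):
        assert parse_pattern("u-x-u-[TS]") == "[LIVFMYW].[LIVFMYW][TS]"
        assert parse_pattern("H-u-H") == "H[LIVFMYW]H"
        assert parse_pattern("Y-x(1,4)-Y") == "Y.{1,4}Y"
        assert parse_pattern("{P}-x(2)") == "[^P].{2,2}"

    def test_planted_motifs_complete(self):
        prot = ("M" + "A" * 40 + "LKVT" + "G" * 30 + "HLH"
                + "S" * 40 + "YLDKY" + "A" * 80)
        h = scan_rcr_motifs(prot)
        assert h.complete
        assert h.motif1.position == 42 and h.motif1.matched == "LKVT"
        assert h.motif2_HUH.position == 76
        assert h.motif3_YY.position == 119
        assert h.tyrosine_offsets == (0, 4)

    def test_histidine_free_incomplete(self):
        prot = "M" + "A" * 40 + "LKVT" + "G" * 30 + "S" * 40 + "YLDKY" + "A" * 40
        h = scan_rcr_motifs(prot)
        assert h.motif2_HUH is None
        assert not h.complete

    def test_reversed_order_incomplete(self):
        prot = ("M" + "A" * 40 + "YLDKY" + "G" * 30 + "HLH"
                + "S" * 40 + "LKVT" + "A" * 80)
        h = scan_rcr_motifs(prot)
        assert h.motif1 and h.motif2_HUH and h.motif3_YY
        assert not h.complete

    def test_too_short_errors(self):
        with pytest.raises(ProviscopeError):
            scan_rcr_motifs("MAAAY")

    @pytest.mark.parametrize("seed", range(100))
    def test_individual_matches_equal_naive_scan(self, seed):
        """Leftmost per-motif matches agree with an explicit-loop oracle
        on random proteins (several proteins per case, ~500 total)."""
        rng = np.random.default_rng(seed)
        for _ in range(5):
            prot = random_protein(rng, int(rng.integers(60, 150)))
            h = scan_rcr_motifs(prot)
            if h.complete:
                # a consistent triple re-anchors motif I on the first
                # *consistent* match, which the naive scan does not model
                continue
            m1, m2, m3 = scan_motifs_naive(prot)
            assert (h.motif1.position if h.motif1 else None) == m1
            assert (h.motif2_HUH.position if h.motif2_HUH else None) == m2
            got3 = (h.motif3_YY.position,
                    len(h.motif3_YY.matched) - 2) if h.motif3_YY else None
            assert got3 == m3


class TestHydropathy:
    def test_poly_ile_window_exact(self):
        pep = "S" * 5 + "I" * 19 + "S" * 30
        tm = hydropathy_tm(pep)
        assert tm is not None
        assert tm.mean_hydropathy == pytest.approx(
            kyte_doolittle_scale()["I"])
        assert (tm.interval.start, tm.interval.end) == (6, 24)

    def test_poly_arg_absent(self):
        assert hydropathy_tm("R" * 60, threshold=0.1) is None

    def test_window_means_equal_direct_summation(self, rng):
        pep = random_protein(rng, 40)
        scale = kyte_doolittle_scale()
        import numpy as np
        vals = [scale[a] for a in pep]
        manual = [sum(vals[i : i + 19]) / 19 for i in range(40 - 19 + 1)]
        best = int(np.argmax(manual))
        tm = hydropathy_tm(pep, threshold=-10.0)
        assert tm.mean_hydropathy == pytest.approx(manual[best])
        assert tm.interval.start == best + 1

    def test_even_window_rejected(self):
        with pytest.raises(ProviscopeError):
            hydropathy_tm("I" * 30, window=18)

    def test_shorter_than_window_absent(self):
        assert hydropathy_tm("I" * 10) is None

    def test_n_terminal_restriction(self):
        # a strong TM beyond the N-terminal search region is not reported
        pep = "S" * 100 + "I" * 19 + "S" * 5
        assert hydropathy_tm(pep, n_terminal=60) is None


class TestCoiledCoil:
    def test_leucine_zipper_high_probability(self):
        assert coiled_coil_prob("LEALEGK" * 5).max() > 0.9

    def test_poly_gly_low(self):
        assert coiled_coil_prob("G" * 40).max() < 0.05

    def test_locality(self, rng):
        zipper = "LEALESK" * 5
        tail = random_protein(rng, 60)
        p1 = coiled_coil_prob(zipper)
        p2 = coiled_coil_prob(zipper + tail)
        assert np.allclose(p1[:7], p2[:7])

    def test_shift_covariance(self):
        zipper = "LEALESK" * 5
        pad = "G" * 30
        p1 = coiled_coil_prob(pad + zipper + pad)
        p2 = coiled_coil_prob(pad + pad + zipper + pad)
        i1 = int(np.argmax(p1))
        i2 = int(np.argmax(p2))
        assert p1.max() == pytest.approx(p2.max())
        assert i2 - i1 == 30

    def test_deterministic(self, rng):
        p = random_protein(rng, 100)
        assert np.array_equal(coiled_coil_prob(p), coiled_coil_prob(p))

    def test_too_short_errors(self):
        with pytest.raises(ProviscopeError):
            coiled_coil_prob("LEALESK")


def _cassette_setup(seed, **kw):
    contig, truth = synthetic.generate_genome(
        seed, background_length=20000, **kw)
    orfs = find_orfs(contig, 60)
    hits = scan_for_anchors(contig, orfs, synthetic.default_queries())
    assert len(hits) == 1
    return contig, truth, orfs, hits[0]


class TestAssembleCassette:
    def test_canonical_cassette_complete(self):
        _contig, truth, orfs, anchor = _cassette_setup(2)
        cand = assemble_cassette(orfs, anchor)
        assert cand.completeness == "complete"
        roles = cand.roles()
        assert set(roles) == {"MCP", "Rep", "pilot", "scaffold"}
        for role in ("Rep", "MCP", "pilot", "scaffold"):
            tiv = truth.role_orfs[role]
            got = roles[role]
            assert got.strand == tiv.strand
            assert got.interval.end == tiv.end
            assert got.interval.start <= tiv.start
        assert not cand.rep_weak

    def test_scaffold_is_150_codon_orf_between_mcp_and_pilot(self):
        _contig, truth, orfs, anchor = _cassette_setup(4)
        cand = assemble_cassette(orfs, anchor)
        assert cand.scaffold is not None
        assert 120 <= len(cand.scaffold.translation) <= 200
        assert cand.scaffold.interval.start > cand.anchor.orf.interval.end
        assert cand.scaffold.interval.end < cand.pilot[0].interval.start

    def test_rep_deleted_partial(self):
        _contig, truth, orfs, anchor = _cassette_setup(6)
        rep_end = truth.role_orfs["Rep"].end
        pruned = [o for o in orfs if o.interval.end != rep_end]
        cand = assemble_cassette(pruned, anchor)
        assert cand.rep is None
        assert cand.completeness == "partial"

    def test_anchor_not_in_orfs_errors(self):
        _contig, _truth, orfs, anchor = _cassette_setup(8)
        others = [o for o in orfs if o is not anchor.orf]
        with pytest.raises(ProviscopeError, match="anchor/ORF mismatch"):
            assemble_cassette(others, anchor)

    def test_pilot_evidence_on_seed_protein(self):
        pilot = synthetic.default_seed_proteins()["pilot"]["sequence"]
        ev = pilot_evidence(pilot)
        assert ev.tm_segment is not None
        assert ev.tm_segment.interval.start <= 60
        assert ev.coiled_coil_max_prob >= 0.5
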