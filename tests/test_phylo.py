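import numpy as np
import pytest

from proviscope import phylo
from proviscope.genome_io import ProviscopeError
from proviscope.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    map_insertions,
    nj_tree,
    robinson_foulds,
    simulate_wag_pair,
    strip_gap_columns,
    wag_distance,
    wag_model,
)

from conftest import random_protein


class TestMapInsertions:
    def test_self_no_insertions(self, rng):
        ref = random_protein(rng, 120)
        assert map_insertions(ref, ref) == []

    def test_ten_residue_insertion_located(self, rng):
        ref = random_protein(rng, 150)
        block = "WWWWWWWWWW"
        target = ref[:70] + block + ref[70:]
        blocks = map_insertions(target, ref)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.length == 10
        assert b.ref_position == 70
        assert b.target_interval == (71, 80)

    def test_five_residue_insertion_below_threshold(self, rng):
        # the reported insertions are strictly longer than 5 aa
        ref = random_protein(rng, 150)
        target = ref[:70] + "WWWWW" + ref[70:]
        assert map_insertions(target, ref) == []

    def test_empty_sequence_errors(self):
        with pytest.raises(ProviscopeError):
            map_insertions("", "ACDE")


class TestStripGapColumns:
    def test_gap_free_unchanged(self):
        aln = {"a": "MKV", "b": "MRV"}
        assert strip_gap_columns(aln) == aln

    def test_all_gap_row_errors(self):
        with pytest.raises(ProviscopeError, match="no complete positions"):
            strip_gap_columns({"a": "MKV", "b": "---"})

    def test_constructed_count(self):
        aln = {"a": "MK-VDE.LIW", "b": "MKAVDEALIW", "c": "MKAVD-ALIW"}
        out = strip_gap_columns(aln)
        assert all(len(v) == 7 for v in out.values())
        assert out["a"] == "MKVDLIW"

    def test_x_treated_as_missing(self):
        out = strip_gap_columns({"a": "MXV", "b": "MKV"})
        assert out == {"a": "MV", "b": "MV"}


class TestWagDistance:
    def test_identical_zero(self):
        s = "MKVLWAARDE" * 10
        assert wag_distance(s, s) == 0.0

    def test_symmetry(self, rng):
        a, b = simulate_wag_pair(0.4, 150, rng)
        assert wag_distance(a, b) == pytest.approx(wag_distance(b, a),
                                                   abs=1e-6)

    def test_no_comparable_sites_errors(self):
        with pytest.raises(ProviscopeError, match="no data"):
            wag_distance("---", "MK-")

    def test_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(7)
        a, b = simulate_wag_pair(0.5, 100, rng)
        from proviscope.phylo import _pair_counts, wag_log_likelihood
        N = _pair_counts(a, b)
        grid = np.arange(0.01, 3.0, 0.0005)
        lls = [wag_log_likelihood(N, t) for t in grid]
        t_grid = float(grid[int(np.argmax(lls))])
        assert wag_distance(a, b) == pytest.approx(t_grid, abs=1e-3)

    def test_monotone_in_divergence_time(self):
        rng = np.random.default_rng(11)
        means = []
        for t in (0.1, 0.3, 0.6, 1.0):
            est = [wag_distance(*simulate_wag_pair(t, 200, rng))
                   for _ in range(25)]
            means.append(np.mean(est))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_transition_matrix_rows_sum_to_one(self):
        P = wag_model().transition_matrix(0.7)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(P > 0)


def _additive_four_taxon():
    # tree: ((A:0.1, B:0.2):0.5, C:0.15, D:0.35) with AB|CD split
    d = {
        ("A", "B"): 0.3, ("A", "C"): 0.75, ("A", "D"): 0.95,
        ("B", "C"): 0.85, ("B", "D"): 1.05, ("C", "D"): 0.5,
    }
    taxa = ("A", "B", "C", "D")
    m = np.zeros((4, 4))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i != j:
                m[i, j] = d[tuple(sorted((x, y)))]
    return DistanceMatrix(taxa, m)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        D = DistanceMatrix(("X", "Y"), np.array([[0, 0.4], [0.4, 0]]))
        tree = nj_tree(D)
        tips = list(tree.tips())
        assert {t.name for t in tips} == {"X", "Y"}
        assert sum(t.length for t in tips) == pytest.approx(0.4)

    def test_four_taxon_additive_recovery(self):
        tree = nj_tree(_additive_four_taxon())
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # branch lengths recovered exactly for an additive matrix
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)

    def test_taxon_permutation_invariance(self):
        D = _additive_four_taxon()
        perm = (2, 0, 3, 1)
        D2 = DistanceMatrix(tuple(D.taxa[i] for i in perm),
                            D.d[np.ix_(perm, perm)])
        assert bipartitions(nj_tree(D)) == bipartitions(nj_tree(D2))

    @pytest.mark.parametrize("seed", range(40))
    def test_random_additive_tree_topology_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        taxa = tuple(f"t{i}" for i in range(n))
        # random additive tree: random topology by sequential attachment
        import skbio
        nodes = [skbio.TreeNode(name=t) for t in taxa[:3]]
        root = skbio.TreeNode(children=nodes)
        for t in taxa[3:]:
            cands = [nd for nd in root.traverse() if nd.parent is not None]
            attach = cands[int(rng.integers(0, len(cands)))]
            parent = attach.parent
            inner = skbio.TreeNode()
            parent.remove(attach)
            inner.append(attach)
            inner.append(skbio.TreeNode(name=t))
            parent.append(inner)
        for nd in root.traverse(include_self=False):
            nd.length = float(rng.uniform(0.05, 0.5))
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = root.find(taxa[i]).distance(root.find(taxa[j]))
                dm[i, j] = dm[j, i] = d
        tree = nj_tree(DistanceMatrix(taxa, dm))
        assert robinson_foulds(tree, root) == 0

    def test_negative_distance_rejected(self):
        with pytest.raises(ProviscopeError):
            DistanceMatrix(("a", "b"), np.array([[0, -0.1], [-0.1, 0]]))


class TestBootstrap:
    def _alignment(self, rng, ncols=60):
        base = random_protein(rng, ncols)
        aln = {"t1": base, "t2": base}
        for name in ("t3", "t4", "t5"):
            aln[name] = random_protein(rng, ncols)
        return aln

    def test_identical_taxa_support_one(self, rng):
        aln = self._alignment(rng)
        _tree, supports = bootstrap_support(aln, n_replicates=25, seed=3)
        # t1 and t2 are identical; every resample preserves their pairing.
        # The canonical side of that split is the complement set.
        key = frozenset({"t3", "t4", "t5"})
        assert supports[key] == 1.0

    def test_single_replicate_supports_binary(self, rng):
        aln = self._alignment(rng)
        _tree, supports = bootstrap_support(aln, n_replicates=1, seed=0)
        assert set(supports.values()) <= {0.0, 1.0}

    def test_seed_reproducibility(self, rng):
        aln = self._alignment(rng)
        _t1, s1 = bootstrap_support(aln, n_replicates=20, seed=42)
        _t2, s2 = bootstrap_support(aln, n_replicates=20, seed=42)
        assert s1 == s2

    def test_low_support_collapsed(self, rng):
        aln = self._alignment(rng)
        tree, supports = bootstrap_support(aln, n_replicates=25, seed=3,
                                           collapse=0.5)
        surviving = bipartitions(tree)
        for split in surviving:
            assert supports.get(split, 1.0) >= 0.5

    def test_short_alignment_rejected(self):
        with pytest.raises(ProviscopeError):
            bootstrap_support({"a": "MKV", "b": "MKV", "c": "MRV"}, 5, 0)
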