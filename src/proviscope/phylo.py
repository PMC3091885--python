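"""Capsid-protein characterization: insertion mapping and distance trees.

Two analyses characterize candidate major capsid proteins:

* :func:`map_insertions` locates insertion blocks (>5 aa by default)
  relative to a reference capsid protein from a pairwise global
  alignment — the gokushovirus-like "mushroom" protrusion loops appear
  as large insertions relative to the microvirus capsid fold.

* A distance phylogeny: pairwise maximum-likelihood distances under the
  WAG amino-acid substitution model, neighbor-joining, and bootstrap
  support from column resampling.  This is a deterministic desk-scale
  stand-in for a full ML topology search; it preserves groupings at the
  fidelity testable on synthetic alignments.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from io import StringIO

import numpy as np
from scipy.optimize import minimize_scalar
from Bio.Align import PairwiseAligner

import skbio
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .genome_io import ProviscopeError
from .homology import load_matrix

__all__ = [
    "InsertionBlock",
    "DistanceMatrix",
    "map_insertions",
    "strip_gap_columns",
    "wag_distance",
    "distance_matrix",
    "nj_tree",
    "nj_newick",
    "bootstrap_support",
    "bipartitions",
    "robinson_foulds",
]

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}


# ---------------------------------------------------------------------------
# insertion mapping


@dataclass(frozen=True)
class InsertionBlock:
    """A target-specific insertion relative to the reference protein."""

    index: int            # ordinal, 1-based, left to right
    ref_position: int     # reference residue after which the block sits
    length: int           # aa
    target_interval: tuple[int, int]  # 1-based residues in the target


def map_insertions(target: str, reference: str,
                   min_len: int = 6) -> list[InsertionBlock]:
    """Insertion blocks in ``target`` relative to ``reference``.

    A pairwise global alignment (BLOSUM62, affine gaps) is scanned for
    maximal runs of reference-gap columns; runs of at least ``min_len``
    residues (default 6, i.e. strictly more than 5 aa) are reported with
    the reference position after which they occur.
    """
    if not target or not reference:
        raise ProviscopeError("empty sequence in insertion mapping")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_matrix()
    aligner.open_gap_score = -12.0   # gap of length k costs 11 + k
    aligner.extend_gap_score = -1.0
    aln = next(iter(aligner.align(target, reference)))
    t_row, r_row = str(aln[0]), str(aln[1])
    blocks: list[InsertionBlock] = []
    ref_pos = 0
    tgt_pos = 0
    run_len = 0
    run_start_tgt = 0
    for tc, rc in zip(t_row, r_row):
        if rc == "-" and tc != "-":
            if run_len == 0:
                run_start_tgt = tgt_pos + 1
            run_len += 1
            tgt_pos += 1
            continue
        if run_len >= min_len:
            blocks.append(InsertionBlock(len(blocks) + 1, ref_pos, run_len,
                                         (run_start_tgt,
                                          run_start_tgt + run_len - 1)))
        run_len = 0
        if tc != "-":
            tgt_pos += 1
        if rc != "-":
            ref_pos += 1
    if run_len >= min_len:
        blocks.append(InsertionBlock(len(blocks) + 1, ref_pos, run_len,
                                     (run_start_tgt,
                                      run_start_tgt + run_len - 1)))
    return blocks


# ---------------------------------------------------------------------------
# alignment utilities


def strip_gap_columns(alignment: dict[str, str]) -> dict[str, str]:
    """Remove every column containing a gap or X in any row."""
    rows = list(alignment.values())
    if not rows or len({len(r) for r in rows}) != 1:
        raise ProviscopeError("ragged alignment")
    keep = [i for i in range(len(rows[0]))
            if all(r[i] not in "-.X" for r in rows)]
    if not keep:
        raise ProviscopeError("no complete positions")
    return {k: "".join(v[i] for i in keep) for k, v in alignment.items()}


# ---------------------------------------------------------------------------
# WAG model


class _WagModel:
    """WAG rate matrix with spectral decomposition for fast P(t)."""

    def __init__(self) -> None:
        ref = importlib.resources.files("proviscope.data") / "wag.tsv"
        lines = [l for l in ref.read_text().splitlines() if l.strip()]
        header = lines[0].split("\t")[1:]
        assert header == list(_AA_ORDER)
        S = np.array([[float(x) for x in line.split("\t")[1:]]
                      for line in lines[1:21]])
        freq_line = lines[21].split("\t")
        pi = np.array([float(x) for x in freq_line[1:]])
        pi = pi / pi.sum()
        R = S * pi[None, :]
        np.fill_diagonal(R, 0.0)
        np.fill_diagonal(R, -R.sum(axis=1))
        mu = -np.sum(pi * np.diag(R))
        R /= mu                      # one expected substitution per unit t
        d = np.sqrt(pi)
        B = (R * d[:, None]) / d[None, :]
        B = (B + B.T) / 2.0          # numerical symmetrization
        w, U = np.linalg.eigh(B)
        self.pi = pi
        self._w = w
        self._left = U / d[None, :].T
        self._right = (U * d[:, None]).T

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._w * t)) @ self._right
        return np.clip(P, 1e-300, None)


_WAG: _WagModel | None = None


def wag_model() -> _WagModel:
    global _WAG
    if _WAG is None:
        _WAG = _WagModel()
    return _WAG


def _pair_counts(a: str, b: str) -> np.ndarray:
    N = np.zeros((20, 20))
    for x, y in zip(a, b):
        i = _AA_INDEX.get(x)
        j = _AA_INDEX.get(y)
        if i is not None and j is not None:
            N[i, j] += 1
    return N


def wag_log_likelihood(N: np.ndarray, t: float) -> float:
    model = wag_model()
    P = model.transition_matrix(t)
    return float(np.sum(N * (np.log(model.pi)[:, None] + np.log(P))))


def simulate_wag_pair(t: float, n_sites: int,
                      rng: np.random.Generator) -> tuple[str, str]:
    """Simulate an aligned sequence pair at divergence ``t`` under WAG.

    Ancestral states are drawn from the stationary frequencies and the
    second sequence from the transition matrix P(t); used for
    parameter-recovery experiments.
    """
    model = wag_model()
    P = model.transition_matrix(t)
    anc = rng.choice(20, size=n_sites, p=model.pi)
    der = np.array([rng.choice(20, p=P[i] / P[i].sum()) for i in anc])
    return ("".join(_AA_ORDER[i] for i in anc),
            "".join(_AA_ORDER[i] for i in der))


def wag_distance(a: str, b: str, t_min: float = 1e-6,
                 t_max: float = 10.0) -> float:
    """Pairwise maximum-likelihood distance (substitutions/site) under WAG.

    Gap and ambiguous columns are removed pairwise; the distance is the
    ``t`` maximizing the sum over sites of ``log(pi_i P_ij(t))``,
    bracketed on ``[t_min, t_max]``.  Identical sequences return 0.
    """
    pairs = [(x, y) for x, y in zip(a, b)
             if x in _AA_INDEX and y in _AA_INDEX]
    if not pairs:
        raise ProviscopeError("no data: zero comparable sites")
    N = _pair_counts("".join(p[0] for p in pairs),
                     "".join(p[1] for p in pairs))
    if N.sum() == np.trace(N):
        return 0.0
    res = minimize_scalar(lambda t: -wag_log_likelihood(N, t),
                          bounds=(t_min, t_max), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


# ---------------------------------------------------------------------------
# distance matrices and neighbor joining


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ProviscopeError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ProviscopeError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ProviscopeError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ProviscopeError("negative distances")


def distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """WAG ML distance matrix from an aligned protein dict."""
    taxa = tuple(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = wag_distance(alignment[taxa[i]],
                                             alignment[taxa[j]])
    return DistanceMatrix(taxa, d)


def nj_tree(D: DistanceMatrix):
    """Unrooted neighbor-joining tree as a scikit-bio TreeNode.

    Negative branch lengths are clamped to zero; for two taxa the result
    is the single edge of length d(1,2) (split evenly across the root).
    """
    n = len(D.taxa)
    if n < 2:
        raise ProviscopeError("need at least 2 taxa")
    if n == 2:
        d = float(D.d[0, 1])
        nwk = f"({D.taxa[0]}:{d / 2:.10g},{D.taxa[1]}:{d / 2:.10g});"
        return skbio.TreeNode.read(StringIO(nwk))
    dm = _SkbioDM(D.d, ids=list(D.taxa))
    return _skbio_nj(dm, neg_as_zero=True)


def nj_newick(D: DistanceMatrix) -> str:
    buf = StringIO()
    nj_tree(D).write(buf)
    return buf.getvalue().strip()


def bipartitions(tree, taxa: set[str] | None = None) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, each as the canonical side.

    The canonical side of a split is the one not containing the
    lexicographically smallest taxon, so label sets compare across
    differently rooted trees.
    """
    tips = {t.name for t in tree.tips()}
    if taxa is None:
        taxa = tips
    anchor = min(taxa)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        if anchor in side:
            side = frozenset(tips - side)
        splits.add(side)
    return splits


def robinson_foulds(tree_a, tree_b) -> int:
    sa, sb = bipartitions(tree_a), bipartitions(tree_b)
    return len(sa ^ sb)


def _resample_columns(alignment: dict[str, str],
                      rng: np.random.Generator) -> dict[str, str]:
    ncol = len(next(iter(alignment.values())))
    idx = rng.integers(0, ncol, size=ncol)
    return {k: "".join(v[i] for i in idx) for k, v in alignment.items()}


def bootstrap_support(alignment: dict[str, str], n_replicates: int = 100,
                      seed: int = 0, collapse: float = 0.5):
    """Bootstrap branch supports for the NJ tree of an alignment.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal branch of the full-data tree is the
    fraction of replicate trees containing the same bipartition.
    Branches below ``collapse`` support are collapsed in the returned
    consensus tree.  Deterministic given the seed.

    Returns ``(tree, supports)`` where supports maps each canonical
    bipartition (frozenset of tip names) to its support.
    """
    if n_replicates < 1:
        raise ProviscopeError("n_replicates must be >= 1")
    ncol = len(next(iter(alignment.values())))
    if ncol < 10:
        raise ProviscopeError("alignment too short for bootstrapping")
    base = strip_gap_columns(alignment)
    tree = nj_tree(distance_matrix(base))
    ref_splits = bipartitions(tree)
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = _resample_columns(base, rng)
        rep_tree = nj_tree(distance_matrix(rep))
        rep_splits = bipartitions(rep_tree)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: c / n_replicates for s, c in counts.items()}
    # annotate and collapse
    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    to_remove = []
    for node in list(tree.non_tips(include_self=False)):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(tips - side)
        if side in supports:
            node.name = f"{supports[side]:.2f}"
            if supports[side] < collapse:
                to_remove.append(node)
    for node in to_remove:
        parent = node.parent
        if parent is None:
            continue
        for child in list(node.children):
            node.remove(child)
            parent.append(child)
        parent.remove(node)
    return tree, supports
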