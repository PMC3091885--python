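"""Capsid-anchored homology search.

Candidate major-capsid-protein (MCP) loci are found by local alignment of
user-supplied seed protein queries against ORF translations.  This is a
database-free, deterministic stand-in for iterative profile searches
seeded with gokushovirus MCPs: the user provides the seed set explicitly
and hits are thresholded on raw substitution-matrix score and percent
identity rather than on E-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import Contig, OrfRecord, ProviscopeError

__all__ = [
    "AlignmentResult",
    "AnchorHit",
    "load_matrix",
    "local_align",
    "scan_for_anchors",
    "DEFAULT_MIN_SCORE",
    "DEFAULT_MIN_IDENTITY",
]

# Score threshold in matrix units and identity floor for anchor calls.
# These must admit gokushovirus-to-BMV level divergence (the seed queries
# are more distant from the target proviruses than microviruses are from
# each other: a full-length capsid homologue at ~25% identity still
# scores several hundred) while excluding chance local alignments, which
# reach the high double digits against composition-biased ORFs; both are
# exposed in the pipeline configuration.
DEFAULT_MIN_SCORE = 120.0
DEFAULT_MIN_IDENTITY = 0.25

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

_BLOSUM62 = None


def load_matrix(path: str | Path | None = None):
    """Load a substitution matrix.

    With no argument, returns BLOSUM62.  Otherwise reads an NCBI-format
    plain-text matrix file.
    """
    global _BLOSUM62
    if path is None:
        if _BLOSUM62 is None:
            _BLOSUM62 = substitution_matrices.load("BLOSUM62")
        return _BLOSUM62
    return substitution_matrices.read(str(path))


@dataclass(frozen=True)
class AlignmentResult:
    """A local protein alignment.

    Residue spans are 1-based inclusive; identity is computed over
    aligned (non-gap) columns only.  An empty result (no positive-scoring
    cell) has score 0 and empty spans.
    """

    score: float
    query_interval: tuple[int, int] | None
    target_interval: tuple[int, int] | None
    identity_fraction: float
    aligned_pairs: int

    @property
    def is_empty(self) -> bool:
        return self.query_interval is None


_EMPTY = AlignmentResult(0.0, None, None, 0.0, 0)


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> PairwiseAligner:
    # NCBI convention: a gap of length k costs gap_open + k * gap_extend,
    # so the aligner's first-gap-position score is -(open + extend)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(gap_open) - abs(gap_extend)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def local_align(query: str, target: str, matrix=None,
                gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Optimal local alignment score with affine gaps.

    Traceback is deterministic (the aligner's first optimal path).  Empty
    input or an all-negative scoring matrix cell yields the empty result.
    """
    if not query or not target:
        return _EMPTY
    if matrix is None:
        matrix = load_matrix()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(query, target)
    if score <= 0:
        return _EMPTY
    aln = next(iter(aligner.align(query, target)))
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    identity = counts.identities / aligned if aligned else 0.0
    qblocks, tblocks = aln.aligned
    q_iv = (int(qblocks[0][0]) + 1, int(qblocks[-1][1]))
    t_iv = (int(tblocks[0][0]) + 1, int(tblocks[-1][1]))
    return AlignmentResult(float(score), q_iv, t_iv, identity, int(aligned))


@dataclass(frozen=True)
class AnchorHit:
    """An ORF anchored to a capsid seed query."""

    orf: OrfRecord
    best_query: str
    alignment: AlignmentResult


def scan_for_anchors(contig: Contig, orfs: list[OrfRecord],
                     queries: list[tuple[str, str]],
                     min_score: float = DEFAULT_MIN_SCORE,
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     matrix=None,
                     gap_open: float = DEFAULT_GAP_OPEN,
                     gap_extend: float = DEFAULT_GAP_EXTEND) -> list[AnchorHit]:
    """Anchor capsid-like ORFs by aligning every query to every ORF.

    For each ORF the best-scoring query is retained; hits must pass both
    ``min_score`` and ``min_identity``.  Results are sorted by genomic
    position.
    """
    if not queries:
        raise ProviscopeError("no seed queries")
    if matrix is None:
        matrix = load_matrix()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    hits = []
    for orf in orfs:
        target = orf.translation
        if not target:
            continue
        best_q, best_s = None, -1.0
        for qid, qseq in queries:
            s = aligner.score(qseq, target)
            if s > best_s:
                best_q, best_s = (qid, qseq), s
        if best_s < min_score:
            continue
        res = local_align(best_q[1], target, matrix, gap_open, gap_extend)
        if res.score >= min_score and res.identity_fraction >= min_identity:
            hits.append(AnchorHit(orf, best_q[0], res))
    hits.sort(key=lambda h: (h.orf.interval.start, h.orf.interval.end))
    return hits
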