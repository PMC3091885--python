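"""Empty-site comparison: pin the attachment core against a provirus-free
relative.

Comparing a provirus-containing genomic region (the "lysogen") with the
homologous provirus-free region of a closely related genome (the
"naive" comparator) reveals the exact chromosomal attachment site: the
naive region carries a single copy of the core that the lysogen carries
duplicated at both provirus junctions.

Anchoring uses a fast global (edit-distance) alignment of the two
regions; the provirus is the large lysogen-only block between the
flanking homology anchors.  Because the duplicated core makes the gap
placement ambiguous at single-base resolution, the junctions are then
refined by locating the dif-like site at each junction and the
duplicated core as the top direct repeat between the two junction
neighborhoods.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .attsites import (
    AttRepeatPair,
    DifConsensus,
    DifSite,
    find_direct_repeats,
    locate_site_around,
    DEFAULT_MIN_TOTAL,
    DEFAULT_MIN_BEST_ARM,
)
from .genome_io import Contig, Interval, ProviscopeError

__all__ = ["EmptySiteResult", "locate_empty_site"]


@dataclass(frozen=True)
class EmptySiteResult:
    """Outcome of a lysogen / provirus-free region comparison."""

    core: str                       # duplicated att core sequence
    core_interval_naive: Interval | None
    left_junction: Interval         # core occurrence at the left junction
    right_junction: Interval        # core occurrence at the right junction
    duplicated: bool
    junction_mismatches: int        # substitutions between the two copies
    provirus_interval: Interval     # inferred provirus extent in the lysogen
    dif_sites: tuple[DifSite | None, DifSite | None] = (None, None)
    note: str = ""


_CIG = re.compile(r"(\d+)([=XIDM])")

# exact-match runs at least this long cannot occur by chance between
# unrelated sequence and therefore mark true homology anchors
_LONG_MATCH = 30


def _clean_junction(naive_seq: str, lysogen_seq: str):
    """0-based start of the long anchor block after the insertion gap.

    A global edit-distance alignment of the naive region against the
    lysogen region leaves the anchor block *following* the large
    insertion intact, while chance single-base matches shred the block
    preceding it (the traceback threads co-optimal matches through the
    inserted sequence).  Only exact-match runs of ``_LONG_MATCH`` bp or
    more count as anchors.  Returns ``(block_start0, gap_len,
    anchor_len_after, boundary)`` where ``boundary`` is true when the
    maximal gap touches a sequence end (missing flank), or ``(None, 0,
    0, False)`` when there is no gap.
    """
    res = edlib.align(naive_seq, lysogen_seq, mode="NW", task="path")
    t = 0
    blocks = []
    for num, op in _CIG.findall(res["cigar"]):
        n = int(num)
        if op in "=XM":
            if op == "=" and n >= _LONG_MATCH:
                blocks.append((t, n))
            t += n
        elif op == "D":       # consumes lysogen (target) only
            t += n
        # 'I' consumes the naive query only; no lysogen advance
    if not blocks:
        return None, 0, 0, False
    gaps = []
    if blocks[0][0] > 0:
        gaps.append((blocks[0][0], blocks[0][0], True))
    for (s1, n1), (s2, _n2) in zip(blocks, blocks[1:]):
        gaps.append((s2 - (s1 + n1), s2, False))
    last_end = blocks[-1][0] + blocks[-1][1]
    if len(lysogen_seq) - last_end > 0:
        gaps.append((len(lysogen_seq) - last_end, len(lysogen_seq), True))
    if not gaps:
        return None, 0, 0, False
    gap_len, next_start, boundary = max(gaps)
    after = sum(n for s, n in blocks if s >= next_start)
    return next_start, gap_len, after, boundary


def locate_empty_site(lysogen_region: Contig, naive_region: Contig,
                      consensus: DifConsensus | None = None,
                      min_anchor: int = 200, min_insert: int = 500,
                      max_mismatch: int = 0, min_core: int = 8,
                      junction_halfwidth: int = 120,
                      min_total: int = DEFAULT_MIN_TOTAL,
                      min_best_arm: int = DEFAULT_MIN_BEST_ARM) -> EmptySiteResult:
    """Infer the provirus extent and attachment core from an empty-site
    comparison.

    Raises ``no provirus detected`` when the two regions align end to
    end without a large lysogen-only insertion (a valid negative), and
    ``one-sided homology`` when an anchor of at least ``min_anchor``
    aligned bases is missing on one side of the insertion.
    """
    if consensus is None:
        consensus = DifConsensus.default()
    lys = lysogen_region.sequence
    nav = naive_region.sequence
    # two passes: the forward alignment yields a clean right junction,
    # the reversed alignment a clean left junction (the shredded side
    # flips with the traceback direction)
    jr_fwd, gap_fwd, right_anchor, bound_fwd = _clean_junction(nav, lys)
    jr_rev, gap_rev, left_anchor, bound_rev = _clean_junction(
        nav[::-1], lys[::-1])
    if jr_fwd is None and jr_rev is None:
        raise ProviscopeError("no provirus detected")
    if (jr_fwd is not None and bound_fwd and gap_fwd >= min_insert) or \
            (jr_rev is not None and bound_rev and gap_rev >= min_insert):
        raise ProviscopeError("one-sided homology")
    if jr_fwd is None or jr_rev is None or \
            min(gap_fwd, gap_rev) < min_insert:
        raise ProviscopeError("no provirus detected")
    if left_anchor < min_anchor or right_anchor < min_anchor:
        raise ProviscopeError("one-sided homology")
    # raw, core-ambiguous lysogen junctions (1-based)
    raw_l = len(lys) - jr_rev + 1
    raw_r = jr_fwd
    if raw_r - raw_l < min_insert - 2 * len(consensus):
        raise ProviscopeError("no provirus detected")

    lys = lysogen_region.sequence
    h = junction_halfwidth
    wl_lo = max(1, raw_l - h)
    wl_hi = min(len(lys), raw_l + h)
    wr_lo = max(1, raw_r - h)
    wr_hi = min(len(lys), raw_r + h)
    window_l = lys[wl_lo - 1 : wl_hi]
    window_r = lys[wr_lo - 1 : wr_hi]

    pairs = find_direct_repeats(window_l, window_r, min_len=min_core,
                                max_mismatch=max_mismatch,
                                consensus=consensus)
    core = ""
    duplicated = False
    mism = 0
    if pairs:
        top = pairs[0]
        dist_l = Interval(wl_lo + top.attL.start - 1,
                          wl_lo + top.attL.end - 1)
        dist_r = Interval(wr_lo + top.attR.start - 1,
                          wr_lo + top.attR.end - 1)
        core = lys[dist_l.start - 1 : dist_l.end]
        duplicated = True
        mism = top.mismatches
        left_junction, right_junction = dist_l, dist_r
    else:
        left_junction = Interval(raw_l, min(raw_l + min_core - 1, len(lys)))
        right_junction = Interval(max(1, raw_r - min_core + 1), raw_r)

    site_l = locate_site_around(lysogen_region, left_junction, consensus,
                                min_total, min_best_arm)
    site_r = locate_site_around(lysogen_region, right_junction, consensus,
                                min_total, min_best_arm)
    start = site_l.interval.start if site_l else left_junction.start
    end = site_r.interval.end if site_r else right_junction.end
    provirus = Interval(start, end)

    core_naive = None
    if core:
        naive = naive_region.sequence
        # the single remaining copy sits near the left-anchor end
        approx = left_junction.start
        lo = max(0, approx - 1 - 3 * h)
        idx = naive.find(core, lo, min(len(naive), approx + 3 * h))
        if idx < 0:
            idx = naive.find(core)
        if idx >= 0:
            core_naive = Interval(idx + 1, idx + len(core))

    note = ""
    if site_l is None or site_r is None:
        note = "no dif-like site at one or both junctions; extent is repeat-based"
    return EmptySiteResult(
        core=core, core_interval_naive=core_naive,
        left_junction=left_junction, right_junction=right_junction,
        duplicated=duplicated, junction_mismatches=mism,
        provirus_interval=provirus, dif_sites=(site_l, site_r), note=note,
    )
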