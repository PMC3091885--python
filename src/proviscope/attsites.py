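"""Attachment-site discovery and provirus boundary delineation.

Integration of microvirus-like proviruses at the chromosome-dimer
resolution site duplicates a short core (13 bp in the best-characterized
case) that then flanks the provirus as direct repeats, each embedded in a
~28-bp dif-like sequence (XerC arm / spacer / XerD arm).  This module

* scores sequences against a partitioned IUPAC dif consensus,
* scans contigs for dif-like sites on both strands,
* finds duplicated direct-repeat cores between two flank windows,
* delineates the provirus extent from the first nucleotide of the left
  dif-like site to the last nucleotide of the right one, and
* locates additional internal dif-like sites near provirus termini.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import importlib.resources

import numpy as np
import pandas as pd
import yaml

from .genome_io import Contig, Interval, ProviscopeError, reverse_complement, span_length

__all__ = [
    "DifConsensus",
    "DifScore",
    "DifSite",
    "AttRepeatPair",
    "iupac_match_count",
    "scan_dif",
    "find_direct_repeats",
    "best_dif_near",
    "delineate_provirus",
    "find_internal_dif",
    "build_logo",
    "IUPAC_SETS",
    "DEFAULT_MIN_TOTAL",
    "DEFAULT_MIN_BEST_ARM",
]

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# Default call thresholds: a dif-like site must match the 28-bp consensus
# at >= 19 positions overall with at least one arm matching at >= 7
# positions (mismatches in real att sites concentrate in the arms, so a
# site must still bind at least one recombinase arm well).
DEFAULT_MIN_TOTAL = 19
DEFAULT_MIN_BEST_ARM = 7


@dataclass(frozen=True)
class DifConsensus:
    """A partitioned IUPAC dif consensus.

    ``left_arm`` (XerC-binding), ``spacer`` and ``right_arm``
    (XerD-binding) are 1-based inclusive coordinate pairs that must tile
    the consensus contiguously.
    """

    iupac: str
    left_arm: tuple[int, int]
    spacer: tuple[int, int]
    right_arm: tuple[int, int]

    def __post_init__(self) -> None:
        bad = set(self.iupac) - set(IUPAC_SETS)
        if bad:
            raise ProviscopeError(f"invalid IUPAC letters {sorted(bad)}")
        la, sp, ra = self.left_arm, self.spacer, self.right_arm
        if not (la[0] == 1 and la[1] + 1 == sp[0] and sp[1] + 1 == ra[0]
                and ra[1] == len(self.iupac)):
            raise ProviscopeError(
                "arms and spacer must tile the consensus contiguously"
            )

    def __len__(self) -> int:
        return len(self.iupac)

    @classmethod
    def default(cls) -> "DifConsensus":
        ref = importlib.resources.files("proviscope.data") / "dif_consensus.yaml"
        return cls.from_yaml_text(ref.read_text())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DifConsensus":
        return cls.from_yaml_text(Path(path).read_text())

    @classmethod
    def from_yaml_text(cls, text: str) -> "DifConsensus":
        raw = yaml.safe_load(text)
        return cls(
            iupac=str(raw["iupac"]).upper(),
            left_arm=tuple(raw["left_arm"]),
            spacer=tuple(raw["spacer"]),
            right_arm=tuple(raw["right_arm"]),
        )

    def reverse_complement(self) -> "DifConsensus":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}
        rc = "".join(comp[c] for c in reversed(self.iupac))
        n = len(self.iupac)
        ra = (n - self.right_arm[1] + 1, n - self.right_arm[0] + 1)
        sp = (n - self.spacer[1] + 1, n - self.spacer[0] + 1)
        la = (n - self.left_arm[1] + 1, n - self.left_arm[0] + 1)
        # after reverse complement the old right arm becomes the left flank
        return DifConsensus(rc, ra, sp, la)


@dataclass(frozen=True)
class DifScore:
    """Per-region IUPAC match counts of a window against the consensus."""

    total_matches: int
    left_arm_matches: int
    spacer_matches: int
    right_arm_matches: int
    strand: str = "+"

    @property
    def best_arm(self) -> int:
        return max(self.left_arm_matches, self.right_arm_matches)


@dataclass(frozen=True)
class DifSite:
    interval: Interval
    strand: str
    score: DifScore


@dataclass(frozen=True)
class AttRepeatPair:
    """A duplicated direct repeat delimiting attL/attR.

    Intervals are relative to whatever sequences the repeats were found
    in (window-relative for :func:`find_direct_repeats`); ``dif_scores``
    holds the best consensus match at/around each repeat.
    """

    attL: Interval
    attR: Interval
    repeat_length: int
    mismatches: int
    dif_scores: tuple[DifScore | None, DifScore | None] = (None, None)

    @property
    def dif_total(self) -> int:
        return sum(s.total_matches for s in self.dif_scores if s is not None)


def _allowed_table(consensus: DifConsensus) -> np.ndarray:
    """(L, 5) boolean: allowed[i, code] for codes A,C,G,T,N.

    N in the scanned sequence (code 4) never matches.
    """
    table = np.zeros((len(consensus), 5), dtype=bool)
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, c in enumerate(consensus.iupac):
        for b in IUPAC_SETS[c]:
            table[i, codes[b]] = True
    return table


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    ).astype(np.int64)


def _region_slices(consensus: DifConsensus):
    return (slice(consensus.left_arm[0] - 1, consensus.left_arm[1]),
            slice(consensus.spacer[0] - 1, consensus.spacer[1]),
            slice(consensus.right_arm[0] - 1, consensus.right_arm[1]))


def iupac_match_count(sequence: str, consensus: DifConsensus,
                      strand: str = "+") -> DifScore:
    """Count per-position IUPAC-compatible matches, partitioned by region."""
    if len(sequence) != len(consensus):
        raise ProviscopeError(
            f"length mismatch: sequence {len(sequence)} vs consensus "
            f"{len(consensus)}"
        )
    table = _allowed_table(consensus)
    codes = _encode(sequence.upper())
    match = table[np.arange(len(consensus)), codes]
    la, sp, ra = _region_slices(consensus)
    return DifScore(int(match.sum()), int(match[la].sum()),
                    int(match[sp].sum()), int(match[ra].sum()), strand)


def _scan_one_strand(codes: np.ndarray, consensus: DifConsensus) -> np.ndarray:
    """(n_windows, 4) columns: total, left, spacer, right matches."""
    L = len(consensus)
    table = _allowed_table(consensus)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    match = table[np.arange(L)[None, :], win]
    la, sp, ra = _region_slices(consensus)
    return np.stack([
        match.sum(axis=1),
        match[:, la].sum(axis=1),
        match[:, sp].sum(axis=1),
        match[:, ra].sum(axis=1),
    ], axis=1)


def scan_dif(contig: Contig | str, consensus: DifConsensus,
             min_total: int = DEFAULT_MIN_TOTAL,
             region_minima: tuple[int, int, int] = (0, 0, 0),
             min_best_arm: int = DEFAULT_MIN_BEST_ARM,
             offset: int = 0) -> list[DifSite]:
    """Scan both strands of a contig for dif-like sites.

    Thresholds: ``min_total`` on overall matches, ``region_minima`` per
    region, and ``min_best_arm`` on the better of the two arms.
    Overlapping passing hits on the same strand are resolved to the best
    score (leftmost on ties).  ``offset`` shifts reported coordinates
    (used when scanning an extracted subsequence).
    """
    seq = contig.sequence if isinstance(contig, Contig) else contig
    L = len(consensus)
    if len(seq) < L:
        return []
    sites: list[DifSite] = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        scores = _scan_one_strand(_encode(s), consensus)
        ok = (
            (scores[:, 0] >= min_total)
            & (scores[:, 1] >= region_minima[0])
            & (scores[:, 2] >= region_minima[1])
            & (scores[:, 3] >= region_minima[2])
            & (np.maximum(scores[:, 1], scores[:, 3]) >= min_best_arm)
        )
        idx = np.flatnonzero(ok)
        cands = []
        for i in idx:
            if strand == "+":
                start = int(i) + 1
            else:
                start = len(seq) - int(i) - L + 1
            cands.append(DifSite(
                Interval(start + offset, start + offset + L - 1, strand),
                strand,
                DifScore(int(scores[i, 0]), int(scores[i, 1]),
                         int(scores[i, 2]), int(scores[i, 3]), strand),
            ))
        # overlap resolution per strand: best score wins, leftmost on ties
        cands.sort(key=lambda d: (-d.score.total_matches, d.interval.start))
        chosen: list[DifSite] = []
        for c in cands:
            if all(not c.interval.overlaps(k.interval) for k in chosen):
                chosen.append(c)
        sites.extend(chosen)
    sites.sort(key=lambda d: (d.interval.start, d.strand))
    return sites


def find_direct_repeats(left_window: str, right_window: str,
                        min_len: int = 8, max_mismatch: int = 0,
                        consensus: DifConsensus | None = None,
                        rank: bool = True) -> list[AttRepeatPair]:
    """All maximal direct-repeat pairs between two windows.

    A pair is a same-length substring occurrence in each window with at
    most ``max_mismatch`` substitutions, maximal in the sense that it
    cannot be extended on either side without violating the budget or
    the window bounds.  Coordinates are window-relative (1-based).
    Ranked by (length desc, mismatches asc, dif total desc).
    """
    if not left_window or not right_window:
        raise ProviscopeError("empty repeat-search window")
    if min_len < 8:
        raise ProviscopeError("min_len must be >= 8")
    n, m = len(left_window), len(right_window)
    a = _encode(left_window)
    b = _encode(right_window)
    pairs: list[AttRepeatPair] = []
    for d in range(-(n - min_len), m - min_len + 1):
        i0 = max(0, -d)
        j0 = i0 + d
        ln = min(n - i0, m - j0)
        if ln < min_len:
            continue
        mism = (a[i0 : i0 + ln] != b[j0 : j0 + ln]) | \
               (a[i0 : i0 + ln] >= 4) | (b[j0 : j0 + ln] >= 4)
        mism_pos = np.flatnonzero(mism)
        # maximal windows with <= max_mismatch mismatches along the diagonal
        k = max_mismatch
        bounds = np.concatenate(([-1], mism_pos, [ln]))
        nblocks = len(mism_pos)
        for t in range(max(1, nblocks + 1 - k)):
            lo = int(bounds[t]) + 1                            # first usable
            hi = int(bounds[min(t + k + 1, nblocks + 1)]) - 1  # last usable
            length = hi - lo + 1
            if length < min_len:
                continue
            used = int(mism[lo:hi + 1].sum())
            pairs.append(AttRepeatPair(
                Interval(i0 + lo + 1, i0 + hi + 1),
                Interval(j0 + lo + 1, j0 + hi + 1),
                length, used,
            ))
    if consensus is not None:
        pairs = [
            AttRepeatPair(
                p.attL, p.attR, p.repeat_length, p.mismatches,
                (best_dif_near(left_window, p.attL, consensus),
                 best_dif_near(right_window, p.attR, consensus)),
            )
            for p in pairs
        ]
    if rank:
        pairs.sort(key=lambda p: (-p.repeat_length, p.mismatches,
                                  -p.dif_total, p.attL.start, p.attR.start))
    return pairs


def best_dif_near(seq: str, repeat: Interval,
                  consensus: DifConsensus) -> DifScore | None:
    """Best consensus match among windows overlapping a repeat interval.

    Returns the best :class:`DifScore` over both strands regardless of
    thresholds (near-miss scores are informative even when no site would
    be called).
    """
    L = len(consensus)
    lo = max(0, repeat.start - 1 - (L - 1))
    hi = min(len(seq), repeat.end + (L - 1))
    sub = seq[lo:hi]
    if len(sub) < L:
        return None
    best: DifScore | None = None
    for strand in "+-":
        s = sub if strand == "+" else reverse_complement(sub)
        scores = _scan_one_strand(_encode(s), consensus)
        i = int(np.argmax(scores[:, 0]))
        sc = DifScore(int(scores[i, 0]), int(scores[i, 1]),
                      int(scores[i, 2]), int(scores[i, 3]), strand)
        if best is None or sc.total_matches > best.total_matches:
            best = sc
    return best


def locate_site_around(contig: Contig, core: Interval,
                       consensus: DifConsensus,
                       min_total: int = DEFAULT_MIN_TOTAL,
                       min_best_arm: int = DEFAULT_MIN_BEST_ARM) -> DifSite | None:
    """Best passing dif site overlapping a repeat core on the contig."""
    L = len(consensus)
    lo = max(1, core.start - L)
    hi = min(len(contig), core.end + L)
    sites = scan_dif(contig.sequence[lo - 1 : hi], consensus,
                     min_total=min_total, min_best_arm=min_best_arm,
                     offset=lo - 1)
    sites = [s for s in sites if s.interval.overlaps(core)]
    if not sites:
        return None
    return max(sites, key=lambda s: (s.score.total_matches, -s.interval.start))


def delineate_provirus(candidate, best_pair: AttRepeatPair,
                       contig: Contig | None = None,
                       consensus: DifConsensus | None = None,
                       min_total: int = DEFAULT_MIN_TOTAL,
                       min_best_arm: int = DEFAULT_MIN_BEST_ARM):
    """Set the provirus extent from an attachment repeat pair.

    ``best_pair`` must carry contig-absolute coordinates with attL
    entirely upstream of attR.  When the contig and a consensus are
    supplied, each repeat core is expanded to the best dif-like site
    overlapping it, and the extent runs from the first nucleotide of the
    left site to the last nucleotide of the right site (the same size
    convention as the provirus coordinate tables); without a passing
    site the repeat coordinates themselves delimit the extent.

    Returns ``(candidate_with_extent, (site_l, site_r))``.
    """
    from .cassette import with_extent

    attL, attR = best_pair.attL, best_pair.attR
    if not attL.end < attR.start:
        raise ProviscopeError("att ordering violation")
    site_l = site_r = None
    if contig is not None and consensus is not None:
        site_l = locate_site_around(contig, attL, consensus, min_total,
                                    min_best_arm)
        site_r = locate_site_around(contig, attR, consensus, min_total,
                                    min_best_arm)
    start = site_l.interval.start if site_l else attL.start
    end = site_r.interval.end if site_r else attR.end
    if start > end:
        raise ProviscopeError("att ordering violation")
    extent = Interval(start, end, candidate.extent.strand)
    return with_extent(candidate, extent), (site_l, site_r)


def find_internal_dif(contig: Contig, extent: Interval,
                      consensus: DifConsensus,
                      min_total: int = DEFAULT_MIN_TOTAL,
                      min_best_arm: int = DEFAULT_MIN_BEST_ARM,
                      exclude_flank: int | None = None) -> list[tuple[DifSite, int]]:
    """dif-like sites in the proviral interior, with terminus distances.

    The scan is restricted to the interior of ``extent`` excluding
    ``exclude_flank`` bp at each end (default: the consensus length, so
    the flanking att sites themselves are not re-reported).  Each site
    is returned with its distance to the nearest provirus terminus.
    """
    L = len(consensus)
    if exclude_flank is None:
        exclude_flank = L
    lo = extent.start + exclude_flank
    hi = extent.end - exclude_flank
    if hi - lo + 1 < L:
        return []
    sites = scan_dif(contig.sequence[lo - 1 : hi], consensus,
                     min_total=min_total, min_best_arm=min_best_arm,
                     offset=lo - 1)
    out = []
    for s in sites:
        dist = min(s.interval.start - extent.start,
                   extent.end - s.interval.end)
        out.append((s, int(dist)))
    out.sort(key=lambda t: t[0].interval.start)
    return out


def build_logo(att_sequences: list[str], correction: bool = True) -> pd.DataFrame:
    """Per-column information content and letter heights for a set of
    aligned attachment sites.

    Information content per column is ``R = 2 - H - e(n)`` bits, where H
    is the Shannon entropy of the observed base frequencies and ``e(n) =
    3 / (2 n ln 2)`` the small-sample correction (applied when
    ``correction`` is true); R is clamped at 0 and letter heights are
    frequency times R.
    """
    if len(att_sequences) < 2:
        raise ProviscopeError("need at least 2 sequences for a logo")
    lengths = {len(s) for s in att_sequences}
    if len(lengths) != 1:
        raise ProviscopeError("ragged alignment")
    seqs = [s.upper() for s in att_sequences]
    bad = set("".join(seqs)) - set("ACGT")
    if bad:
        raise ProviscopeError(f"logo alphabet must be ACGT, got {sorted(bad)}")
    n = len(seqs)
    ncol = lengths.pop()
    rows = []
    e_n = 3.0 / (2.0 * np.log(2) * n) if correction else 0.0
    for i in range(ncol):
        col = [s[i] for s in seqs]
        freqs = {b: col.count(b) / n for b in "ACGT"}
        h = -sum(f * np.log2(f) for f in freqs.values() if f > 0)
        r = max(0.0, 2.0 - h - e_n)
        row = {"column": i + 1, "bits": r}
        row.update({b: freqs[b] * r for b in "ACGT"})
        rows.append(row)
    return pd.DataFrame(rows, columns=["column", "bits", "A", "C", "G", "T"])
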