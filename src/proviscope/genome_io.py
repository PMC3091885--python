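"""Sequence I/O, coordinate conventions, and ORF calling.

All genomic coordinates in this package are 1-based and inclusive at both
ends, matching the convention used in provirus coordinate tables
(e.g. ``453860..460215``).  Conversion to 0-based half-open indexing
happens only at explicit format boundaries (Python slicing, GFF3 stays
1-based).

The genetic code defaults to the bacterial/archaeal translation table 11
with start codons ATG, GTG and TTG, appropriate for Bacteroidetes hosts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Contig",
    "Interval",
    "OrfRecord",
    "read_fasta",
    "write_fasta",
    "read_protein_fasta",
    "span_length",
    "reverse_complement",
    "find_orfs",
    "extract",
    "write_gff3",
    "write_tsv",
    "load_provirus_table",
]

# IUPAC nucleotide codes accepted on input; degenerate codes are collapsed
# to N because downstream stages only distinguish A/C/G/T from "unknown".
_IUPAC_NT = set("ACGTUNRYSWKMBDHV")
_DEGENERATE = set("RYSWKMBDHV")

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ProviscopeError(ValueError):
    """Base error for user-facing failures."""


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic interval with strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ProviscopeError(
                f"inverted interval: {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ProviscopeError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProviscopeError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ProviscopeError(
                f"invalid alphabet in record {self.id!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A predicted open reading frame.

    The interval includes the stop codon; the translation excludes it.
    ``frame`` is 1-3 on the forward strand and 4-6 on the reverse strand.
    ORFs whose translation is more than 10% X (from Ns in the coding
    region) are flagged rather than discarded.
    """

    interval: Interval
    frame: int
    translation: str
    start_codon: str
    flagged: bool = False

    @property
    def strand(self) -> str:
        return self.interval.strand


def span_length(start: int, end: int) -> int:
    """Length in bp of the 1-based inclusive span ``start..end``.

    This is the size convention used for provirus extents: the distance
    between the first and the last nucleotides of the two dif-like sites
    flanking the proviral region.
    """
    if start > end:
        raise ProviscopeError(f"inverted interval: {start}..{end}")
    return end - start + 1


def _normalize(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    chars = set(seq)
    bad = chars - _IUPAC_NT
    if bad:
        raise ProviscopeError(
            f"invalid alphabet in record {record_id!r}: {sorted(bad)}"
        )
    if chars & _DEGENERATE:
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[Contig]:
    """Read nucleotide FASTA into a list of :class:`Contig`, order preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ProviscopeError(f"no records in {path}")
    contigs = []
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise ProviscopeError(f"empty sequence for record {rec.id!r}")
        contigs.append(
            Contig(rec.id, _normalize(seq, rec.id), rec.description)
        )
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            header = c.description if c.description.startswith(c.id) else c.id
            fh.write(f">{header}\n")
            for i in range(0, len(c.sequence), wrap):
                fh.write(c.sequence[i : i + wrap] + "\n")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA as (id, sequence) pairs."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ProviscopeError(f"no records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ProviscopeError(f"empty sequence for record {rec.id!r}")
        out.append((rec.id, seq))
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract(contig: Contig, interval: Interval) -> str:
    """Sequence of ``interval`` on its strand (reverse-complemented for '-')."""
    if interval.end > len(contig):
        raise ProviscopeError(
            f"interval {interval.start}..{interval.end} exceeds contig "
            f"{contig.id} length {len(contig)}"
        )
    s = contig.sequence[interval.start - 1 : interval.end]
    return reverse_complement(s) if interval.strand == "-" else s


def _translate(nt: str, table: int, start_codon: str,
               start_codons: Sequence[str]) -> str:
    aa = str(Seq(nt).translate(table=table))
    if aa and start_codon in start_codons and aa[0] != "M":
        aa = "M" + aa[1:]
    return aa


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    )


def _codon_positions(codes: np.ndarray, codons: Sequence[str]) -> np.ndarray:
    """0-based positions where one of ``codons`` starts (any frame)."""
    if codes.size < 3:
        return np.empty(0, dtype=np.int64)
    h = codes[:-2].astype(np.int32) * 25 + codes[1:-1] * 5 + codes[2:]
    targets = np.array(
        [_CODE[c[0]] * 25 + _CODE[c[1]] * 5 + _CODE[c[2]] for c in codons]
    )
    return np.flatnonzero(np.isin(h, targets))


def _scan_strand(seq: str, min_codons: int, table: int,
                 start_codons: Sequence[str]) -> list[tuple[int, int, int, str, str]]:
    """ORFs on the forward reading of ``seq``.

    Returns (start0, stop_end0_exclusive, frame0, start_codon, translation)
    with 0-based coordinates; the span includes the stop codon.
    """
    codes = _encode(seq)
    stop_pos = _codon_positions(codes, STOP_CODONS)
    start_pos = _codon_positions(codes, start_codons)
    out = []
    for f in range(3):
        stops = stop_pos[stop_pos % 3 == f]
        starts = start_pos[start_pos % 3 == f]
        prev = f - 3  # virtual stop before the sequence
        si = 0
        for stop in stops:
            # first allowed start strictly after the previous stop codon
            while si < len(starts) and starts[si] < prev + 3:
                si += 1
            j = si
            while j < len(starts) and starts[j] < stop:
                start = starts[j]
                n_codons = (stop - start) // 3
                if n_codons >= min_codons:
                    nt = seq[start:stop]
                    aa = _translate(nt, table, seq[start : start + 3], start_codons)
                    out.append((int(start), int(stop) + 3, f,
                                seq[start : start + 3], aa))
                break
            prev = stop
    return out


def find_orfs(contig: Contig, min_codons: int = 60, table: int = 11,
              start_codons: Sequence[str] = DEFAULT_START_CODONS) -> list[OrfRecord]:
    """Call ORFs on both strands in all six frames.

    An ORF runs from an allowed start codon to the next in-frame stop
    (reported span includes the stop codon); only the first start after
    each preceding stop is reported, and the translation (stop excluded)
    must be at least ``min_codons`` long.  Results are sorted by start
    coordinate.
    """
    if min_codons < 1:
        raise ProviscopeError("min_codons must be >= 1")
    n = len(contig)
    orfs: list[OrfRecord] = []
    for strand in "+-":
        seq = contig.sequence if strand == "+" else reverse_complement(contig.sequence)
        for start0, end0, f, start_codon, aa in _scan_strand(
            seq, min_codons, table, start_codons
        ):
            if strand == "+":
                iv = Interval(start0 + 1, end0, "+")
                frame = f + 1
            else:
                iv = Interval(n - end0 + 1, n - start0, "-")
                frame = f + 4
            flagged = aa.count("X") > 0.10 * len(aa)
            orfs.append(OrfRecord(iv, frame, aa, start_codon, flagged))
    orfs.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    return orfs


@dataclass
class Gff3Feature:
    seqid: str
    type: str
    start: int
    end: int
    strand: str = "+"
    score: str = "."
    attributes: dict = field(default_factory=dict)


def write_gff3(features: Iterable[Gff3Feature], path: str | Path,
               source: str = "proviscope") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ft in features:
            attrs = ";".join(f"{k}={v}" for k, v in ft.attributes.items())
            fh.write(
                f"{ft.seqid}\t{source}\t{ft.type}\t{ft.start}\t{ft.end}\t"
                f"{ft.score}\t{ft.strand}\t.\t{attrs or '.'}\n"
            )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_provirus_table() -> pd.DataFrame:
    """Reference coordinates of the known BMV proviruses.

    Rows with ``coordinates_consistent == 1`` have printed coordinate
    pairs whose span reproduces the reported size and can be used for
    coordinate arithmetic; the others are retained for reference only.
    """
    ref = importlib.resources.files("proviscope.data") / "bmv_coordinates.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")
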