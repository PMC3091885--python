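"""End-to-end provirus discovery pipeline with validated configuration.

Stages run in order: ORF calling -> capsid anchoring -> cassette
annotation -> attachment-site delineation -> internal dif scan ->
(optional) capsid insertion mapping.  Candidates without an attachment
repeat pair are still reported, with near-miss dif scores, since real
proviruses exist whose att sites fall below any fixed threshold or are
truncated with the contig.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import attsites, cassette as cassette_mod, homology
from .attsites import AttRepeatPair, DifConsensus, DifSite
from .cassette import CassetteRules, ProvirusCandidate
from .genome_io import (
    Contig,
    Gff3Feature,
    Interval,
    ProviscopeError,
    find_orfs,
    read_fasta,
    read_protein_fasta,
    write_gff3,
    write_tsv,
)
from .phylo import InsertionBlock, map_insertions

log = logging.getLogger("proviscope")

__all__ = ["PipelineConfig", "validate_config", "ProvirusReport",
           "run_pipeline", "report_dataframe", "report_gff3"]


_RANGES = {
    "min_codons": (1, 10_000),
    "min_score": (0.0, 1e6),
    "min_identity": (0.0, 1.0),
    "gap_open": (0.0, 100.0),
    "gap_extend": (0.0, 100.0),
    "min_total": (1, None),          # bounded by consensus length
    "min_best_arm": (0, None),
    "repeat_min_len": (8, 100),
    "repeat_max_mismatch": (0, 10),
    "flank_outside": (50, 10_000),
    "flank_inside": (0, 1000),
    "cc_min_prob": (0.0, 1.0),
    "tm_threshold": (-4.5, 4.5),
    "seed": (0, 2**31 - 1),
}

_DEFAULTS = {
    "contigs": None,
    "queries": None,
    "consensus": None,            # path; None -> packaged default
    "matrix": None,               # path; None -> BLOSUM62
    "reference_capsid": None,     # path to a protein FASTA, optional
    "out_dir": ".",
    "seed": 0,
    "min_codons": 60,
    "min_score": homology.DEFAULT_MIN_SCORE,
    "min_identity": homology.DEFAULT_MIN_IDENTITY,
    "gap_open": homology.DEFAULT_GAP_OPEN,
    "gap_extend": homology.DEFAULT_GAP_EXTEND,
    "min_total": attsites.DEFAULT_MIN_TOTAL,
    "min_best_arm": attsites.DEFAULT_MIN_BEST_ARM,
    # att repeat search: windows extend this far beyond / inside each
    # cassette end.  Provirus sizes exceed the gene span by well under a
    # kilobase, so 500 bp outside brackets the atts; the inside overlap
    # is generous (300 bp) because called ORF 5' boundaries can extend
    # upstream of the true gene start to an earlier in-frame start codon,
    # shifting the apparent cassette edge past the attachment site.
    "flank_outside": 500,
    "flank_inside": 300,
    "repeat_min_len": 8,
    "repeat_max_mismatch": 0,
    "cc_min_prob": 0.5,
    "tm_threshold": 1.6,
}


@dataclass(frozen=True)
class PipelineConfig:
    values: dict
    provenance: dict  # key -> "default" | "user"

    def __getattr__(self, key):
        try:
            return self.values[key]
        except KeyError as e:
            raise AttributeError(key) from e


def validate_config(raw: dict | str | None) -> PipelineConfig:
    """Fill defaults, reject unknown keys, and range-check thresholds."""
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ProviscopeError(f"unknown config keys: {sorted(unknown)}")
    values = dict(_DEFAULTS)
    values.update(raw)
    provenance = {k: ("user" if k in raw else "default") for k in values}
    consensus = (DifConsensus.from_yaml(values["consensus"])
                 if values["consensus"] else DifConsensus.default())
    for key, (lo, hi) in _RANGES.items():
        v = values[key]
        if hi is None:
            hi = len(consensus)
        if not (lo <= v <= hi):
            raise ProviscopeError(
                f"config value {key}={v} outside allowed range [{lo}, {hi}]"
            )
    for key in values:
        log.debug("config %s=%r (%s)", key, values[key], provenance[key])
    return PipelineConfig(values, provenance)


@dataclass
class CandidateReport:
    contig_id: str
    candidate: ProvirusCandidate
    att_pair: AttRepeatPair | None          # contig-absolute coordinates
    att_sites: tuple[DifSite | None, DifSite | None]
    internal_dif: list
    near_miss: tuple | None                  # best sub-threshold dif scores
    insertions: list[InsertionBlock] = field(default_factory=list)


@dataclass
class ProvirusReport:
    candidates: list[CandidateReport]
    config: PipelineConfig


def _analyse_anchor(contig, orfs, anchor, consensus, cfg) -> CandidateReport:
    rules = CassetteRules(cc_min_prob=cfg.cc_min_prob,
                          tm_threshold=cfg.tm_threshold)
    cand = cassette_mod.assemble_cassette(orfs, anchor, rules)
    cs, ce = cand.extent.start, cand.extent.end
    wl_lo = max(1, cs - cfg.flank_outside)
    wl_hi = min(len(contig), cs + cfg.flank_inside)
    wr_lo = max(1, ce - cfg.flank_inside)
    wr_hi = min(len(contig), ce + cfg.flank_outside)
    window_l = contig.sequence[wl_lo - 1 : wl_hi]
    window_r = contig.sequence[wr_lo - 1 : wr_hi]
    pairs = attsites.find_direct_repeats(
        window_l, window_r, min_len=cfg.repeat_min_len,
        max_mismatch=cfg.repeat_max_mismatch, consensus=consensus,
    )
    # an attachment pair must have dif-like context at both repeats:
    # Xer-mediated integration duplicates a core embedded in dif sites,
    # so bare repeats without consensus support are not att candidates
    pairs = [p for p in pairs
             if all(s is not None and s.total_matches >= cfg.min_total
                    and s.best_arm >= cfg.min_best_arm
                    for s in p.dif_scores)]
    att_pair = None
    att_sites: tuple[DifSite | None, DifSite | None] = (None, None)
    near_miss = None
    internal = []
    if pairs:
        # equally ranked pairs: prefer the one closest to the cassette ends
        best_key = (pairs[0].repeat_length, pairs[0].mismatches,
                    pairs[0].dif_total)
        tied = [p for p in pairs
                if (p.repeat_length, p.mismatches, p.dif_total) == best_key]
        def dist(p):
            return (abs((wl_lo + p.attL.end - 1) - cs)
                    + abs((wr_lo + p.attR.start - 1) - ce))
        top = min(tied, key=dist)
        att_pair = AttRepeatPair(
            Interval(wl_lo + top.attL.start - 1, wl_lo + top.attL.end - 1),
            Interval(wr_lo + top.attR.start - 1, wr_lo + top.attR.end - 1),
            top.repeat_length, top.mismatches, top.dif_scores,
        )
        cand, att_sites = attsites.delineate_provirus(
            cand, att_pair, contig, consensus,
            min_total=cfg.min_total, min_best_arm=cfg.min_best_arm,
        )
        internal = attsites.find_internal_dif(
            contig, cand.extent, consensus,
            min_total=cfg.min_total, min_best_arm=cfg.min_best_arm,
        )
    else:
        # report the best (sub-threshold) dif match in each flank window
        near_l = attsites.best_dif_near(
            window_l, Interval(1, len(window_l)), consensus)
        near_r = attsites.best_dif_near(
            window_r, Interval(1, len(window_r)), consensus)
        near_miss = (near_l, near_r)
    return CandidateReport(contig.id, cand, att_pair, att_sites,
                           internal, near_miss)


def run_pipeline(config: PipelineConfig | dict | None,
                 contigs: list[Contig] | None = None,
                 queries: list[tuple[str, str]] | None = None) -> ProvirusReport:
    """Run anchor -> cassette -> att -> internal-dif on every contig.

    Contigs and queries may be passed in memory or referenced by path in
    the configuration.  An empty anchor set yields an empty report (not
    an error).  Deterministic given configuration and inputs.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    cfg = config
    if contigs is None:
        if not cfg.contigs:
            raise ProviscopeError("no contigs supplied")
        contigs = read_fasta(cfg.contigs)
    if queries is None:
        if not cfg.queries:
            raise ProviscopeError("no seed queries")
        queries = read_protein_fasta(cfg.queries)
    consensus = (DifConsensus.from_yaml(cfg.consensus) if cfg.consensus
                 else DifConsensus.default())
    matrix = homology.load_matrix(cfg.matrix)
    reference = None
    if cfg.reference_capsid:
        reference = read_protein_fasta(cfg.reference_capsid)[0]

    reports = []
    for contig in contigs:
        t0 = time.perf_counter()
        orfs = find_orfs(contig, min_codons=cfg.min_codons)
        anchors = homology.scan_for_anchors(
            contig, orfs, queries, min_score=cfg.min_score,
            min_identity=cfg.min_identity, matrix=matrix,
            gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
        )
        log.info("contig=%s orfs=%d anchors=%d elapsed=%.2fs", contig.id,
                 len(orfs), len(anchors), time.perf_counter() - t0)
        contig_reports = []
        for anchor in anchors:
            rep = _analyse_anchor(contig, orfs, anchor, consensus, cfg)
            if reference is not None:
                rep.insertions = map_insertions(anchor.orf.translation,
                                                reference[1])
            contig_reports.append(rep)
        reports.extend(_dedupe(contig_reports))
    return ProvirusReport(reports, cfg)


def _dedupe(reports: list[CandidateReport]) -> list[CandidateReport]:
    """Collapse candidates with overlapping extents to the best anchor.

    Several ORFs of one provirus can pass the anchor threshold (for
    example a capsid fragment in another frame); only the strongest
    anchor per locus is reported.
    """
    kept: list[CandidateReport] = []
    for rep in sorted(reports,
                      key=lambda r: -r.candidate.anchor.alignment.score):
        if all(not rep.candidate.extent.overlaps(k.candidate.extent)
               for k in kept):
            kept.append(rep)
    kept.sort(key=lambda r: r.candidate.extent.start)
    return kept


def report_dataframe(report: ProvirusReport) -> pd.DataFrame:
    """One row per candidate, mirroring the provirus coordinate tables."""
    rows = []
    for r in report.candidates:
        c = r.candidate
        roles = c.roles()
        row = {
            "contig": r.contig_id,
            "start": c.extent.start,
            "end": c.extent.end,
            "size_bp": c.size_bp,
            "strand": c.extent.strand,
            "completeness": c.completeness,
            "roles": ",".join(sorted(roles)),
            "att_found": r.att_pair is not None,
        }
        if r.att_pair:
            p = r.att_pair
            row.update({
                "attL": f"{p.attL.start}..{p.attL.end}",
                "attR": f"{p.attR.start}..{p.attR.end}",
                "repeat_length": p.repeat_length,
                "repeat_mismatches": p.mismatches,
            })
            for name, score in zip(("attL", "attR"), p.dif_scores):
                if score:
                    row[f"{name}_dif_matches"] = score.total_matches
                    row[f"{name}_arm_matches"] = (
                        f"{score.left_arm_matches}/{score.spacer_matches}"
                        f"/{score.right_arm_matches}")
        elif r.near_miss:
            for name, score in zip(("attL", "attR"), r.near_miss):
                if score:
                    row[f"{name}_near_miss_matches"] = score.total_matches
        row["internal_dif"] = ";".join(
            f"{s.interval.start}..{s.interval.end}({s.strand},{dist}bp)"
            for s, dist in r.internal_dif)
        row["insertions"] = ";".join(
            f"{b.index}:ref{b.ref_position}+{b.length}aa"
            for b in r.insertions)
        rows.append(row)
    return pd.DataFrame(rows)


def report_gff3(report: ProvirusReport) -> list[Gff3Feature]:
    feats = []
    for i, r in enumerate(report.candidates, 1):
        c = r.candidate
        pid = f"provirus{i}"
        feats.append(Gff3Feature(r.contig_id, "provirus", c.extent.start,
                                 c.extent.end, c.extent.strand,
                                 attributes={"ID": pid,
                                             "Completeness": c.completeness}))
        for role, orf in c.roles().items():
            feats.append(Gff3Feature(
                r.contig_id, "CDS", orf.interval.start, orf.interval.end,
                orf.strand, attributes={"ID": f"{pid}.{role}",
                                        "Role": role, "Parent": pid}))
        if r.att_pair:
            for name, iv, score in (("attL", r.att_pair.attL,
                                     r.att_pair.dif_scores[0]),
                                    ("attR", r.att_pair.attR,
                                     r.att_pair.dif_scores[1])):
                feats.append(Gff3Feature(
                    r.contig_id, "attachment_site", iv.start, iv.end, "+",
                    score=str(score.total_matches) if score else ".",
                    attributes={"ID": f"{pid}.{name}", "Role": name,
                                "Parent": pid}))
        for s, dist in r.internal_dif:
            feats.append(Gff3Feature(
                r.contig_id, "attachment_site", s.interval.start,
                s.interval.end, s.strand,
                score=str(s.score.total_matches),
                attributes={"ID": f"{pid}.internal_dif", "Role": "internal",
                            "Parent": pid,
                            "TerminusDistance": str(dist)}))
    return feats


def write_report(report: ProvirusReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(report_dataframe(report), out / "proviruses.tsv")
    write_gff3(report_gff3(report), out / "proviruses.gff3")
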