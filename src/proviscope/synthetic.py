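"""Synthetic genomes with implanted provirus cassettes and ground truth.

The generator emulates the structures the pipeline is built to detect: a
Bacteroidetes-like background contig (i.i.d. nucleotides, GC 0.43) with
an implanted ~4.6-5.2 kb cassette carrying Rep-MCP-scaffold-pilot genes
on one strand, flanked by two 28-bp dif-like sites that share an
identical duplicated core (the attachment site, 13 bp by default) and
optionally carrying one additional internal dif-like site near the right
provirus terminus.  Every output is bit-reproducible given (parameters,
seed), and a :class:`SyntheticTruth` table records implant coordinates,
role ORFs, the att core, and all planted dif sites for
parameter-recovery tests.

Seed proteins are synthetic designed sequences generated
deterministically in code: the Rep seed carries the three
rolling-circle-replication motifs at fixed positions, the pilot seed an
N-terminal hydrophobic (transmembrane-like) stretch and a heptad-repeat
(coiled-coil) block.  Divergence is applied as an exact count of
protein-level substitutions (round(divergence * length)), with
motif/TM/heptad positions protected so that detectability is controlled
by the divergence parameter alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .attsites import DifConsensus, IUPAC_SETS
from .genome_io import Contig, Interval, ProviscopeError, reverse_complement

__all__ = [
    "SyntheticTruth",
    "default_seed_proteins",
    "generate_background",
    "mutate_protein",
    "back_translate",
    "synthesize_cassette",
    "implant",
    "make_empty_site_pair",
    "generate_genome",
    "DEFAULTS",
]

# Study-condition defaults for end-to-end recovery experiments.
DEFAULTS = dict(
    background_length=100_000,
    gc_fraction=0.43,
    divergence=0.3,
    core_len=13,
    dif_mutations=3,
    scaffold_codons=150,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

# spacer insulator: stop codons in all three forward frames, no start
# codons on either strand, so gene ORF boundaries stay where planted
_INSULATOR = "TAACTAGCTGA"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one implanted provirus."""

    provirus_extent: Interval           # attL site start .. attR site end
    att_core: str                       # duplicated core sequence
    att_core_left: Interval             # core occurrence inside attL site
    att_core_right: Interval            # core occurrence inside attR site
    role_orfs: dict                     # role -> Interval (ATG..stop, incl)
    dif_instances: list                 # (Interval, strand, n_mutations)
    internal_dif: Interval | None
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def provirus_size(self) -> int:
        return len(self.provirus_extent)


# ---------------------------------------------------------------------------
# seed proteins

_SEED_CACHE: dict | None = None


def _random_protein(rng: np.random.Generator, n: int) -> list[str]:
    return ["M"] + [_AA[i] for i in rng.integers(0, 20, size=n - 1)]


def default_seed_proteins() -> dict[str, dict]:
    """Deterministic synthetic seed proteins for the three conserved roles.

    Returns ``{role: {"sequence": str, "protected": frozenset[int]}}``
    with 0-based protected positions (feature residues that mutation must
    not touch).
    """
    global _SEED_CACHE
    if _SEED_CACHE is not None:
        return _SEED_CACHE
    rng = np.random.default_rng(7_421_983)

    rep = _random_protein(rng, 350)
    rep[40:44] = list("LKVT")      # motif I  (u-x-u-[TS])
    rep[74:77] = list("HLH")       # motif II (H-u-H)
    rep[120:125] = list("YLDKY")   # motif III with the twin tyrosines
    rep_protected = frozenset({0} | set(range(40, 44)) | set(range(74, 77))
                              | set(range(120, 125)))

    mcp = _random_protein(rng, 650)
    mcp_protected = frozenset({0})

    pilot = _random_protein(rng, 350)
    tm_pool = "ILVF"
    pilot[4:27] = [tm_pool[i] for i in rng.integers(0, 4, size=23)]
    pilot[120:162] = list("LEALESK" * 6)
    pilot_protected = frozenset({0} | set(range(4, 27)) | set(range(120, 162)))

    _SEED_CACHE = {
        "Rep": {"sequence": "".join(rep), "protected": rep_protected},
        "MCP": {"sequence": "".join(mcp), "protected": mcp_protected},
        "pilot": {"sequence": "".join(pilot), "protected": pilot_protected},
    }
    return _SEED_CACHE


def default_queries() -> list[tuple[str, str]]:
    """The undiverged MCP seed, as the anchor-scan query set."""
    return [("MCP_seed", default_seed_proteins()["MCP"]["sequence"])]


# ---------------------------------------------------------------------------
# primitives


def generate_background(length: int, gc_fraction: float = 0.43,
                        seed: int | np.random.Generator = 0) -> Contig:
    """I.i.d. background contig at the stated GC content."""
    if length < 1000:
        raise ProviscopeError("background length must be >= 1000")
    if not 0 < gc_fraction < 1:
        raise ProviscopeError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    p = [(1 - gc_fraction) / 2, gc_fraction / 2,
         gc_fraction / 2, (1 - gc_fraction) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return Contig(f"background_gc{gc_fraction:g}", seq)


def mutate_protein(protein: str, divergence: float,
                   protected: frozenset = frozenset(),
                   rng: np.random.Generator | None = None) -> str:
    """Substitute exactly ``round(divergence * len)`` unprotected residues.

    Each chosen residue is replaced by a uniformly drawn different amino
    acid, so overall identity to the input is 1 - divergence (up to
    rounding).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(protein)
    count = int(round(divergence * n))
    pool = np.array([i for i in range(n) if i not in protected])
    if count > len(pool):
        raise ProviscopeError(
            "divergence too high to preserve protected positions"
        )
    out = list(protein)
    for i in rng.choice(pool, size=count, replace=False):
        choices = [a for a in _AA if a != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


_BACK_TABLE: dict[str, list[str]] | None = None


def _codon_map() -> dict[str, list[str]]:
    global _BACK_TABLE
    if _BACK_TABLE is None:
        table = CodonTable.unambiguous_dna_by_id[11]
        inv: dict[str, list[str]] = {}
        for codon, aa in sorted(table.forward_table.items()):
            inv.setdefault(aa, []).append(codon)
        _BACK_TABLE = inv
    return _BACK_TABLE


def back_translate(protein: str, rng: np.random.Generator,
                   start_codon: str = "ATG") -> str:
    """Back-translate with uniform codon choice per amino acid (seeded).

    The initial residue is encoded by ``start_codon`` so the gene begins
    at a canonical start.
    """
    inv = _codon_map()
    codons = [start_codon]
    for aa in protein[1:]:
        opts = inv[aa]
        codons.append(opts[rng.integers(0, len(opts))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, n: int, gc: float = 0.43) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _spacer(rng: np.random.Generator) -> str:
    return (_random_nt(rng, int(rng.integers(2, 20))) + _INSULATOR
            + _random_nt(rng, int(rng.integers(2, 20))))


# ---------------------------------------------------------------------------
# cassette synthesis


def synthesize_cassette(seed_proteins: dict | None = None,
                        divergence: float = 0.3,
                        scaffold_codons: int = 150,
                        seed: int | np.random.Generator = 0):
    """Build a provirus gene cassette as one nucleotide string.

    Genes are arranged Rep-MCP-scaffold-pilot on the forward strand with
    short insulated spacers; each seed protein is mutated at the stated
    divergence (protected feature positions untouched) and
    back-translated with uniform codon usage.

    Returns ``(cassette_sequence, role_map)`` where ``role_map`` maps
    role to ``(start0, end0_exclusive, protein)`` with 0-based
    cassette-relative coordinates including the stop codon.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    if seed_proteins is None:
        seed_proteins = default_seed_proteins()
    scaffold_seq = "".join(_random_protein(rng, scaffold_codons))
    genes = []
    for role in ("Rep", "MCP", "scaffold", "pilot"):
        if role == "scaffold":
            prot, protected = scaffold_seq, frozenset({0})
        else:
            prot = seed_proteins[role]["sequence"]
            protected = seed_proteins[role]["protected"]
        mutated = mutate_protein(prot, divergence, protected, rng)
        genes.append((role, mutated, back_translate(mutated, rng) + "TAA"))
    parts = []
    role_map = {}
    offset = 0
    for i, (role, prot, nt) in enumerate(genes):
        if i > 0:
            sp = _spacer(rng)
            parts.append(sp)
            offset += len(sp)
        role_map[role] = (offset, offset + len(nt), prot)
        parts.append(nt)
        offset += len(nt)
    cassette = "".join(parts)
    if not 4000 <= len(cassette) <= 6700:
        raise ProviscopeError(
            f"cassette length {len(cassette)} outside the expected window"
        )
    return cassette, role_map


# ---------------------------------------------------------------------------
# implantation


def _instantiate(consensus: DifConsensus, rng: np.random.Generator) -> list[str]:
    return [IUPAC_SETS[c][rng.integers(0, len(IUPAC_SETS[c]))]
            for c in consensus.iupac]


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    opts = [b for b in "ACGT" if b != base]
    return opts[rng.integers(0, 3)]


def _max_common_run(s1: str, s2: str) -> int:
    """Longest exact common substring (any offsets) of two short strings."""
    best = 0
    for d in range(-(len(s1) - 1), len(s2)):
        i = max(0, -d)
        j = i + d
        run = 0
        while i < len(s1) and j < len(s2):
            if s1[i] == s2[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
            i += 1
            j += 1
    return best


def implant(background: Contig, cassette: str,
            consensus: DifConsensus | None = None,
            core_len: int = 13, dif_mutations: int = 3,
            internal_dif: bool = True, role_map: dict | None = None,
            seed: int | np.random.Generator = 0) -> tuple[Contig, SyntheticTruth]:
    """Insert a cassette flanked by dif-like sites sharing a duplicated core.

    The two flanking sites are copies of one consensus instantiation
    carrying an identical ``core_len``-bp core at the same internal
    offset; each copy is mutated at up to ``dif_mutations`` positions
    outside the core.  One mutation per site is placed immediately
    adjacent to the core (post-core in attL, pre-core in attR) so that
    the duplicated region is exactly the core — matching the imperfect
    direct repeats observed at real integration sites, where only the
    recombination core is identical.  Optionally one internal dif-like
    site is planted near the right provirus terminus (as seen in several
    real proviruses).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    if consensus is None:
        consensus = DifConsensus.default()
    L = len(consensus)
    if dif_mutations < 0:
        raise ProviscopeError("dif_mutations must be >= 0")
    if core_len >= L - 1:
        raise ProviscopeError("core must be shorter than the consensus")

    # core offset: keep one position on each side of the core inside the
    # site, and keep either flank shorter than the core so no flank-only
    # exact repeat can outrank the duplicated core
    lo = max(2, L - 2 * core_len + 1)
    hi = min(L - core_len, core_len + 1)
    if lo > hi:
        lo = hi = max(2, min(L - core_len, (L - core_len + 2) // 2))
    p = int(rng.integers(lo, hi + 1))  # 1-based core start within the site

    inst = _instantiate(consensus, rng)
    core = "".join(inst[p - 1 : p - 1 + core_len])
    att_l, att_r = list(inst), list(inst)
    core_idx = set(range(p - 1, p - 1 + core_len))

    muts_l: set[int] = set()
    muts_r: set[int] = set()
    if dif_mutations >= 1:
        # one mutation per site immediately adjacent to the core (post-core
        # in attL, pre-core in attR) confines the duplicated region to
        # exactly the core; with dif_mutations=0 both sites stay perfect
        # consensus copies and the whole site is the duplicated repeat
        muts_l.add(p - 1 + core_len)      # post-core boundary, 0-based
        muts_r.add(p - 2)                 # pre-core boundary, 0-based
        att_l[p - 1 + core_len] = _mutate_base(att_l[p - 1 + core_len], rng)
        att_r[p - 2] = _mutate_base(att_r[p - 2], rng)
        # extra mutations never touch the two boundary positions, so the
        # forced attL/attR mismatches flanking the core cannot be cancelled
        boundary = {p - 2, p - 1 + core_len}
        for att, muts in ((att_l, muts_l), (att_r, muts_r)):
            extra = int(rng.integers(0, dif_mutations))  # total <= budget
            candidates = [i for i in range(L)
                          if i not in core_idx and i not in muts
                          and i not in boundary]
            for i in rng.choice(candidates, size=min(extra, len(candidates)),
                                replace=False):
                att[i] = _mutate_base(att[i], rng)
                muts.add(int(i))

    cassette_ext = cassette
    internal_iv = None
    internal_strand = "+"
    pad_before = 0
    if internal_dif:
        # run-breaking mutations plus rejection sampling guarantee the
        # internal site never shares a core-length exact run with either
        # flanking site, so it cannot outrank the duplicated att core
        att_l_s, att_r_s = "".join(att_l), "".join(att_r)
        for _attempt in range(100):
            inst2 = _instantiate(consensus, rng)
            for f in (0.25, 0.5, 0.75):
                i = int(round(L * f)) - 1 + int(rng.integers(-1, 2))
                i = min(max(i, 0), L - 1)
                inst2[i] = _mutate_base(inst2[i], rng)
            site2 = "".join(inst2)
            internal_strand = "+" if rng.integers(0, 2) == 0 else "-"
            if internal_strand == "-":
                site2 = reverse_complement(site2)
            if max(_max_common_run(site2, att_l_s),
                   _max_common_run(site2, att_r_s)) < core_len:
                break
        else:
            raise ProviscopeError("could not place a distinct internal site")
        pad1 = _random_nt(rng, int(rng.integers(80, 181)))
        pad2 = _random_nt(rng, int(rng.integers(120, 201)))
        pad_before = len(cassette) + len(pad1)
        cassette_ext = cassette + pad1 + site2 + pad2
    else:
        cassette_ext = cassette + _random_nt(rng, int(rng.integers(100, 251)))

    bg = background.sequence
    slack = len(bg) - len(cassette_ext) - 2 * L
    if slack <= 0:
        raise ProviscopeError("background too short for the implant")
    margin = min(1500, slack // 3)
    pos0 = int(rng.integers(margin, len(bg) - len(cassette_ext) - 2 * L - margin + 1))

    lysogen_seq = (bg[:pos0] + "".join(att_l) + cassette_ext
                   + "".join(att_r) + bg[pos0:])
    contig = Contig(f"synthetic_lysogen", lysogen_seq,
                    f"synthetic lysogen (seed={seed_val})")

    att_l_iv = Interval(pos0 + 1, pos0 + L)
    att_r_start = pos0 + L + len(cassette_ext) + 1
    att_r_iv = Interval(att_r_start, att_r_start + L - 1)
    extent = Interval(att_l_iv.start, att_r_iv.end)
    dif_instances = [
        (att_l_iv, "+", len(muts_l)),
        (att_r_iv, "+", len(muts_r)),
    ]
    if internal_dif:
        int_start = pos0 + L + pad_before + 1
        internal_iv = Interval(int_start, int_start + L - 1)
        dif_instances.append((internal_iv, internal_strand, 3))

    role_orfs = {}
    if role_map:
        for role, (s0, e0, _prot) in role_map.items():
            role_orfs[role] = Interval(pos0 + L + s0 + 1, pos0 + L + e0, "+")

    truth = SyntheticTruth(
        provirus_extent=extent,
        att_core=core,
        att_core_left=Interval(pos0 + p, pos0 + p + core_len - 1),
        att_core_right=Interval(att_r_start + p - 1,
                                att_r_start + p - 1 + core_len - 1),
        role_orfs=role_orfs,
        dif_instances=dif_instances,
        internal_dif=internal_iv,
        seed=int(seed_val),
        params=dict(core_len=core_len, dif_mutations=dif_mutations,
                    internal_dif=internal_dif, consensus=consensus.iupac),
    )
    return contig, truth


def make_empty_site_pair(lysogen: Contig, truth: SyntheticTruth) -> Contig:
    """The provirus-free (pre-integration) version of a lysogen contig.

    Deletes the provirus and one att copy, leaving a single core at the
    junction.
    """
    ext = truth.provirus_extent
    seq = (lysogen.sequence[: ext.start - 1] + truth.att_core
           + lysogen.sequence[ext.end :])
    return Contig("synthetic_naive", seq, "provirus-free comparator")


def generate_genome(seed: int, background_length: int | None = None,
                    gc_fraction: float | None = None,
                    divergence: float | None = None,
                    core_len: int | None = None,
                    dif_mutations: int | None = None,
                    internal_dif: bool = True,
                    consensus: DifConsensus | None = None):
    """One synthetic lysogen genome at the default study conditions.

    Returns ``(contig, truth)``.  All stages of the pipeline can be
    exercised against the returned truth table.
    """
    cfg = dict(DEFAULTS)
    for k, v in dict(background_length=background_length,
                     gc_fraction=gc_fraction, divergence=divergence,
                     core_len=core_len, dif_mutations=dif_mutations).items():
        if v is not None:
            cfg[k] = v
    rng = np.random.default_rng(seed)
    bg = generate_background(cfg["background_length"], cfg["gc_fraction"], rng)
    cassette, role_map = synthesize_cassette(
        divergence=cfg["divergence"], scaffold_codons=cfg["scaffold_codons"],
        seed=rng,
    )
    contig, truth = implant(
        bg, cassette, consensus=consensus, core_len=cfg["core_len"],
        dif_mutations=cfg["dif_mutations"], internal_dif=internal_dif,
        role_map=role_map, seed=rng,
    )
    truth = SyntheticTruth(
        **{**truth.__dict__, "seed": seed,
           "params": {**truth.params, **cfg}},
    )
    return contig, truth
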