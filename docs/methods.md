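# Methods

This note documents the models, scoring schemes, parameter choices and
numerical conventions behind `proviscope`, and what the synthetic-data
experiments do and do not demonstrate.

## Coordinates and sizes

All genomic coordinates are 1-based and inclusive; `span_length(s, e) =
e − s + 1`. A provirus extent runs from the first nucleotide of the
left *dif*-like site to the last nucleotide of the right one, matching
the size convention of published provirus coordinate tables. The bundled
table of known proviruses marks three rows whose printed coordinate
pairs do not reproduce the reported size (one partial provirus at a
contig end, one apparent typographic error, one plain inconsistency);
those rows are excluded from arithmetic checks by a
`coordinates_consistent` flag rather than silently corrected.

## ORF calling

Both strands, all six frames, bacterial translation table 11, start
codons {ATG, GTG, TTG}; an ORF runs from the first allowed start after
the preceding in-frame stop to the next stop (span includes the stop,
translation excludes it), with a minimum translation length (default 60
codons). N translates to X; ORFs over 10 % X are flagged, not dropped.
A consequence used throughout: 3′ ends are stop-anchored and exact,
while 5′ starts can extend upstream of a true gene start to an earlier
in-frame start codon. Downstream stages are designed around this
asymmetry (see flank windows below).

## Capsid anchoring

Local alignment is Smith–Waterman with affine gaps via
`Bio.Align.PairwiseAligner`, using the NCBI gap convention: a gap of
length k costs `gap_open + k·gap_extend` (defaults 11/1, BLOSUM62).
An independent three-state dynamic-programming oracle in the test suite
pins this convention down exactly. Anchor calls require score ≥ 120
matrix units and identity ≥ 0.25 over aligned columns. The identity
floor admits capsid homologues at gokushovirus-to-BMV divergence (a
full-length capsid match at 25 % identity scores several hundred); the
score floor sits well above the chance-score regime, which reaches the
high double digits for composition-biased ORF translations (measured on
the synthetic background; the threshold was calibrated against the
requirement of zero false anchors on provirus-free contigs while
retaining anchors at 40 % protein divergence). Candidates whose extents
overlap are collapsed to the strongest anchor, since several ORFs of
one provirus can pass the threshold.

## Cassette annotation

*Rep*: PROSITE-like motif patterns, defaults `u-x-u-[TS]` (motif I),
`H-u-H` (motif II, the HUH signature), `Y-x(1,4)-Y` (motif III, the two
catalytic tyrosines of superfamily-I RCR initiators; the gap must be
tyrosine-free), with inter-motif spacers of 10–60 and 15–80 residues.
The exact published motif alignments are figure-only, so these
defaults encode the superfamily description and are fully configurable.
Assignment takes the nearest upstream same-strand ORF with a complete
motif set, falling back (flagged weaker) to motif III alone.

*Pilot*: requires both an N-terminal transmembrane-like window — the
maximal 19-residue window by mean Kyte–Doolittle hydropathy starting
within the first 60 residues, threshold 1.6 — and a coiled-coil
probability ≥ 0.5.

*Coiled-coil score*: the scorer uses a residue × heptad-position (a–g)
propensity table shipped as swappable package data. Core positions a/d
favor bulky aliphatics, e/g favor charged residues, b/c/f are weakly
selective. For each window (14/21/28) and each of the seven frames the
geometric mean of positional propensities is computed; the best frame's
score is mapped to a probability by a two-Gaussian transform `P =
Gcc/(Gcc + 30·Gglob)`. The globular component of each window's
transform matches the empirical distribution of best-frame scores on
random sequences under this table; the coiled-coil component is centred
on canonical heptad-repeat scores, with a deliberately sharp width for
the noisy 14-residue window. This calibration gives a ~0.3 % false-call
rate on random 350-residue proteins while canonical leucine zippers
score ≈ 1. A single-column propensity scale proved inseparable here:
maximizing over frames and windows drives the score maxima of random
sequences into the zipper range, which is why the table is positional.

*Scaffold*: positional only — an ORF strictly between MCP and pilot of
120–200 codons. Sequence conservation of scaffolding proteins is too
weak to require.

## Attachment sites

The *dif* model is configuration data: a partitioned IUPAC consensus
(left/XerC arm, spacer, right/XerD arm), shipped with the canonical
28-bp enterobacterial *dif* (11/6/11) as default. Match counting is
per-position IUPAC compatibility; N in the subject never matches. Site
calls require ≥ 19/28 total matches and ≥ 7 matches in at least one
arm (imperfect matches in real att sites concentrate in the arms);
both strands are always scanned and overlapping same-strand calls
resolve to the best score, leftmost on ties. All thresholds are
config-exposed; no published cutoff exists, so near-miss best scores
are always reported for candidates without a passing pair (real cases
exist where no *dif*-like flank passes any fixed threshold).

Repeat search: all maximal direct-repeat pairs between a left and a
right flank window (default: 500 bp beyond each cassette end plus
300 bp inside; the generous inside overlap absorbs upstream-extended
ORF starts), minimum length 8, default 0 mismatches, ranked by length,
then mismatches, then *dif* score, with ties broken toward the cassette
ends. Pairs must have *dif*-like context at both repeats — Xer-mediated
integration duplicates a core embedded in *dif* sites, so a bare repeat
without consensus support is not an att candidate (this also rejects
the occasional chance ≥ 13 bp exact repeat between 800 bp windows).
Delineation expands each repeat core to the best passing *dif* site
overlapping it and sets the extent site-start to site-end; without a
passing site the repeat coordinates themselves delimit the extent.
Internal *dif*-like sites are then reported from a scan of the
proviral interior (excluding one consensus length at each end) with
their distance to the nearest terminus.

Logo: per-column information `R = 2 − H − e(n)` bits with the
small-sample correction `e(n) = 3/(2·n·ln 2)` (default on; the
acceptance hand-values are computed with it off), heights = frequency ×
R, R clamped at zero.

## Empty-site comparison

Anchoring uses global edit-distance alignment (edlib) rather than the
affine protein engine: the flanks are long, highly similar nucleotide
regions and the quantity of interest is the position of the homology
break, not a similarity score. Two subtleties drive the design. First,
co-optimal traceback threads chance single-base matches through the
inserted provirus, so the insertion cannot be read off a single gap
operation; only exact-match runs ≥ 30 bp (impossible by chance) count
as anchors. Second, the shredding systematically lands on one side of
the insertion, so the alignment is run twice — forward for the right
junction, on reversed sequences for the left. Junctions are then
refined exactly as in the att stage: the duplicated core is the top
direct repeat between ±120 bp junction windows (0 mismatches by
default — the recombination core is identical by definition, tolerance
available as a parameter), and the provirus interval runs between the
*dif* sites located at the junctions. Degenerate outcomes are explicit:
`no provirus detected` when the regions align end-to-end, `one-sided
homology` when an anchor is missing on one side. A limitation: when the
naive region is much longer than the lysogen region the reversed pass
can be fully shredded; the boundary signal of the informative pass
still drives the error classification.

## Phylogenetics

Insertion mapping reports maximal runs of reference-gap columns longer
than 5 aa from a global pairwise alignment, each with the reference
residue after which it sits.

Distances are pairwise maximum-likelihood under WAG: the exchangeability
matrix and stationary frequencies ship as a data file (values match the
published model); the rate matrix is scaled to one expected substitution
per unit time and exponentiated by spectral decomposition of the
pi-symmetrized form. The distance maximizes the sum over comparable
sites (gap/X columns removed pairwise) of `log(π_i P_ij(t))`, bracketed
on [1e-6, 10] (bounded Brent, xatol 1e-8); identical sequences return
exactly 0. Trees are neighbor-joining (scikit-bio, negative branch
lengths clamped to zero; the two-taxon case is a single edge of length
d split across the root). Bootstrap resamples columns with replacement
with a seeded generator; branch support is the fraction of replicate
trees containing the same bipartition (bipartitions canonicalized by
the side not containing the smallest taxon label), and branches below
0.5 are collapsed in the returned consensus. Full ML topology search,
rate heterogeneity and model selection are out of scope: the published
tree additionally depends on externally computed and manually edited
alignments, which no re-run can reproduce; the distance stand-in
preserves groupings at the fidelity testable on simulated data.

## Synthetic data: what it emulates, what it does not

The generator implants a Rep–MCP–scaffold–pilot cassette (synthetic
designed seed proteins with the detection features built in: planted
RCR motifs, an N-terminal hydrophobic stretch, a heptad block) into an
i.i.d. background at GC 0.43 (Bacteroidetes-like). Divergence is an
exact count of protein substitutions, `round(d·n)`, at seeded uniform
positions outside protected feature residues, so identity to the seed
is 1 − d and detectability is controlled by the divergence parameter
alone; back-translation draws codons uniformly (codon bias is
irrelevant to every tested stage). Genes are separated by 15–49 bp
spacers containing a stop-in-all-frames insulator with no start codons
on either strand, so planted ORF boundaries are stable. Default study
conditions: 100 kb background, divergence 0.3, 13 bp core, up to 3
mutations per *dif* site.

The att structure is built for exact-recovery testing: both flanking
sites are copies of one consensus instantiation sharing the core at the
same internal offset (offset drawn so that neither flank-only segment
can form a core-length repeat); one mutation per site sits immediately
adjacent to the core (post-core in attL, pre-core in attR), confining
the duplicated region to exactly the core, and extra mutations never
touch those boundary positions. With `dif_mutations=0` both sites stay
perfect consensus copies — then the whole site is the duplicated
repeat, and exact core recovery is intentionally not guaranteed. The
optional internal site carries three run-breaking mutations and is
rejection-sampled until it shares no core-length exact run with either
flanking site, so it cannot outrank the true pair. The provirus-free
comparator deletes the provirus and one att copy, leaving a single bare
core at the junction.

Passing the recovery experiments therefore shows that the pipeline
inverts this generative model exactly under realistic noise — it does
not show performance on real contigs, where gene order can vary,
flanks diverge between strains, att sites drift far from any fixed
consensus (two real proviruses have no detectable *dif*-like flanks),
and capsid homology can fall below any fixed identity floor. Those
effects are exactly why every threshold is configuration, not code.

## Problem sizes

The recovery experiments use 100 genomes of 100 kb for the full
pipeline, 30–50 pairs of 20 kb regions for the empty-site comparison,
200 replicates of 100 sites for distance recovery, and 20 four-taxon
matrices for NJ — sizes chosen so the whole suite and the acceptance
script each complete in about a minute on one CPU while keeping the
binomial error of every rate estimate well inside its acceptance
margin.

## Known limitations

- Anchor sensitivity is bounded by single-query local alignment; there
  is no profile/PSSM iteration, so remote homologues that only an
  iterative search would find are missed by design (an external search
  tool can be slotted in upstream of `scan_for_anchors`).
- No E-value statistics; thresholds are raw matrix scores.
- The coiled-coil and TM predictors are self-contained
  re-implementations of the classic window methods, calibrated on this
  package's propensity table — they are discriminators for cassette
  annotation, not general-purpose structure predictors.
- `find_direct_repeats` is exact-maximal by construction but quadratic
  in window length; windows are bounded (~1 kb) by the att search
  design.
- The empty-site comparison assumes a single insertion between
  colinear regions (≤ ~100 kb each); no rearrangements.
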