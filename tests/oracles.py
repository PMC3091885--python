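"""Independent brute-force oracles used to validate the optimized
implementations.  Everything here is written as plainly as possible and
shares no code with the package internals it checks."""

STOPS = {"TAA", "TAG", "TGA"}


def orfs_bruteforce(seq, min_codons, starts=("ATG", "GTG", "TTG")):
    """Six-frame ORF scan by walking codons from every start codon.

    Returns a set of (start, end, strand) 1-based inclusive coordinates
    (stop codon included), keeping only the first start per stop.
    """
    n = len(seq)
    comp = str.maketrans("ACGTN", "TGCAN")
    found = {}
    for strand, s in (("+", seq), ("-", seq.translate(comp)[::-1])):
        for i in range(n - 2):
            if s[i : i + 3] not in starts:
                continue
            j = i
            while j + 3 <= n:
                if s[j : j + 3] in STOPS:
                    if (j - i) // 3 >= min_codons:
                        key = (strand, j)
                        if key not in found or i < found[key][0]:
                            found[key] = (i, j + 2)
                    break
                j += 3
    out = set()
    for (strand, _j), (i, e) in found.items():
        if strand == "+":
            out.add((i + 1, e + 1, "+"))
        else:
            out.add((n - e, n - i, "-"))
    return out


def smith_waterman_affine(a, b, matrix, gap_open, gap_extend):
    """Local alignment score by explicit 3-state dynamic programming."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0,
                          M[i - 1][j - 1] + s,
                          X[i - 1][j - 1] + s,
                          Y[i - 1][j - 1] + s)
            best = max(best, M[i][j])
    return best


def iupac_matches_naive(seq, consensus_iupac, iupac_sets):
    return sum(1 for s, c in zip(seq, consensus_iupac)
               if s != "N" and s in iupac_sets[c])


def dif_scan_naive(seq, consensus, min_total, min_best_arm, iupac_sets):
    """Position-by-position dif scan on both strands (no overlap
    resolution); returns {(start, strand): total_matches}."""
    comp = str.maketrans("ACGTN", "TGCAN")
    L = len(consensus.iupac)
    la = consensus.left_arm
    ra = consensus.right_arm
    out = {}
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(comp)[::-1]
        for i in range(len(s) - L + 1):
            win = s[i : i + L]
            total = iupac_matches_naive(win, consensus.iupac, iupac_sets)
            left = iupac_matches_naive(win[la[0] - 1 : la[1]],
                                       consensus.iupac[la[0] - 1 : la[1]],
                                       iupac_sets)
            right = iupac_matches_naive(win[ra[0] - 1 : ra[1]],
                                        consensus.iupac[ra[0] - 1 : ra[1]],
                                        iupac_sets)
            if total >= min_total and max(left, right) >= min_best_arm:
                start = i + 1 if strand == "+" else len(s) - i - L + 1
                out[(start, strand)] = total
    return out


def direct_repeats_naive(left, right, min_len, max_mismatch):
    """All maximal repeat pairs by checking every start pair.

    For each (i, j) the longest window with at most ``max_mismatch``
    substitutions is grown; a pair is maximal if the window cannot be
    covered by the pair starting one position earlier.
    """
    n, m = len(left), len(right)

    def max_len(i, j):
        mism = 0
        k = 0
        last_ok = 0
        while i + k < n and j + k < m:
            if left[i + k] != right[j + k] or left[i + k] == "N":
                mism += 1
                if mism > max_mismatch:
                    break
            k += 1
            last_ok = k
        return last_ok

    out = set()
    for i in range(n):
        for j in range(m):
            L = max_len(i, j)
            if L < min_len:
                continue
            if i > 0 and j > 0 and max_len(i - 1, j - 1) >= L + 1:
                continue  # contained in a longer pair
            mism = sum(1 for k in range(L) if left[i + k] != right[j + k])
            out.add((i + 1, j + 1, L, mism))
    return out


def scan_motifs_naive(protein, bulky="LIVFMYW"):
    """Leftmost occurrences of the three RCR motif patterns by explicit
    loops (motif I: u-x-u-[TS]; motif II: H-u-H; motif III: Y-x(1,4)-Y
    with a tyrosine-free gap)."""
    m1 = m2 = m3 = None
    for i in range(len(protein) - 3):
        a, _, c, d = protein[i : i + 4]
        if a in bulky and c in bulky and d in "TS":
            m1 = i + 1
            break
    for i in range(len(protein) - 2):
        a, b, c = protein[i : i + 3]
        if a == "H" and b in bulky and c == "H":
            m2 = i + 1
            break
    for i in range(len(protein)):
        if protein[i] != "Y":
            continue
        for g in range(1, 5):
            j = i + 1 + g
            if j < len(protein) and protein[j] == "Y" and \
                    "Y" not in protein[i + 1 : j]:
                m3 = (i + 1, g)
                break
        if m3:
            break
    return m1, m2, m3
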