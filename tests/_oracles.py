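"""Independent brute-force oracles used to cross-check the fast paths.

Each oracle is written from the definition, not from the implementation:
the ORF oracle walks back per ATG; the palindrome oracle tests every
(loop position, loop length) pair position-by-position; the IUPAC oracle
expands degenerate patterns to explicit alternations.
"""

import itertools
import math

from baculokit import genome_io as gio
from baculokit import repeat_finder as rf

STOPS = {"TAA", "TAG", "TGA"}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def orf_oracle(g: gio.Genome, min_aa: int) -> set:
    """All canonical ATG..stop ORFs >= min_aa, as (start, end, strand)."""
    n = g.length
    res = set()
    min_cds = 3 * (min_aa + 1)
    for strand in "+-":
        s = g.sequence if strand == "+" else gio.reverse_complement(g.sequence)

        def codon(p):
            if g.is_circular:
                return "".join(s[(p + t) % n] for t in range(3))
            if p < 0 or p + 3 > n:
                return None
            return s[p : p + 3]

        for i in range(n):
            if codon(i) != "ATG":
                continue
            # canonical iff no in-frame ATG between the previous stop and i
            canonical = True
            k, steps = i - 3, 0
            while True:
                if not g.is_circular and k < 0:
                    break
                if g.is_circular and steps * 3 >= n:
                    canonical = False  # stop-free frame: no defined segment
                    break
                c = codon(k)
                if c in STOPS:
                    break
                if c == "ATG":
                    canonical = False
                    break
                k -= 3
                steps += 1
            if not canonical:
                continue
            j, steps = i + 3, 0
            while True:
                c = codon(j)
                if c is None:
                    break
                if c in STOPS:
                    cds_len = j + 3 - i
                    if min_cds <= cds_len and (not g.is_circular
                                               or cds_len <= n):
                        if strand == "+":
                            res.add((i % n + 1, (i + cds_len - 1) % n + 1, "+"))
                        else:
                            st = n - (i % n)
                            en = n - ((i + cds_len - 1) % n)
                            res.add((en, st, "-"))
                    break
                j += 3
                steps += 1
                if g.is_circular and steps * 3 > n:
                    break
    return res


def palindrome_oracle(g: gio.Genome, min_arm, max_loop, rate, max_arm):
    """O(n^2)-style scan over every (loop start, loop length) pair."""
    s = g.sequence + g.sequence if g.is_circular else g.sequence
    n = g.length
    results = {}
    for gap in range(max_loop + 1):
        for l in range(1, len(s)):
            mism = 0
            best = None
            for k in range(max_arm):
                li, ri = l - 1 - k, l + gap + k
                if li < 0 or ri >= len(s):
                    break
                if COMP.get(s[li]) != s[ri]:
                    mism += 1
                a = k + 1
                if a >= min_arm and mism <= math.floor(a * rate):
                    best = (a, mism)
            if best:
                a, m = best
                start0 = l - a
                span = 2 * a + gap
                if g.is_circular:
                    if span > n:
                        continue
                    key = (start0 % n, span, gap)
                else:
                    key = (start0, span, gap)
                prev = results.get(key)
                if prev is None or (a, -m) > (prev[0], -prev[1]):
                    results[key] = (a, m)
    pals = []
    for (start0, span, gap), (a, m) in results.items():
        e1 = (start0 + span - 1) % n + 1 if g.is_circular else start0 + span
        iv = gio.FeatureInterval(start0 + 1, e1, "+")
        pals.append(rf.Palindrome(interval=iv, arm_length=a, loop_length=gap,
                                  mismatches=m, at_fraction=0.0))
    return rf._reduce_overlaps(pals, n, g.is_circular)


def iupac_oracle(window: str, pattern: str) -> list:
    """Explicit-alternation expansion of a degenerate pattern."""
    alternatives = ["".join(p) for p in
                    itertools.product(*[IUPAC[c] for c in pattern])]
    hits = []
    for off in range(len(window) - len(pattern) + 1):
        if window[off : off + len(pattern)] in alternatives:
            hits.append(off + 1)
    return hits


def nw_affine_oracle(a, b, match, mismatch, gap_open, gap_extend):
    """Independent affine-gap global DP (gap of length L costs
    open + L * extend); returns the optimal score only."""
    INF = float("inf")
    n, m = len(a), len(b)
    M = [[-INF] * (m + 1) for _ in range(n + 1)]
    X = [[-INF] * (m + 1) for _ in range(n + 1)]
    Y = [[-INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])
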