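"""Palindrome / homologous-region (hr) discovery and ori-like repeat analysis.

An *imperfect palindrome* is an inverted repeat: two arms of equal
length that are reverse complements of each other up to a bounded
mismatch fraction, separated by a loop.  AT-rich clusters of such
palindromes (*hrs*) are the classic enhancer/origin-of-replication
elements of baculovirus genomes; a *non-hr ori* is instead marked by
direct repeats in an AT-rich, hr-adjacent context.

The palindrome scan is exhaustive over all (loop position, loop length)
pairs, vectorised over genome positions; circular genomes are scanned on
a doubled sequence and calls deduplicated modulo the genome length.

The hairpin free-energy score is a documented nearest-neighbour
approximation (stacking terms over matched stem pairs, a hairpin-loop
initiation table, and a flat per-mismatch penalty) — deliberately a
transparent, testable model rather than a full secondary-structure
predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import align as _align
from .genome_io import FeatureInterval, Genome, at_fraction, reverse_complement, subsequence

__all__ = [
    "Palindrome",
    "Hr",
    "DirectRepeatPair",
    "RepeatHit",
    "OriCandidate",
    "find_palindromes",
    "hairpin_delta_g",
    "cluster_hrs",
    "conserved_ends",
    "self_similarity",
    "find_direct_repeats",
    "flag_non_hr_ori",
]


@dataclass
class Palindrome:
    """An imperfect inverted repeat: arms, loop, mismatch count, AT%, ΔG."""

    interval: FeatureInterval
    arm_length: int
    loop_length: int
    mismatches: int
    at_fraction: float
    delta_g: float | None = None

    @property
    def span(self) -> int:
        return 2 * self.arm_length + self.loop_length


@dataclass
class Hr:
    """A homologous region: 1+ clustered palindromes and their envelope."""

    id: int
    interval: FeatureInterval
    palindromes: list[Palindrome]
    end_blocks: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class DirectRepeatPair:
    a: FeatureInterval
    b: FeatureInterval
    unit_length_a: int
    unit_length_b: int
    identity: float


@dataclass
class RepeatHit:
    """One local self-similarity hit (direct or inverted orientation)."""

    a: FeatureInterval
    b: FeatureInterval
    orientation: str  # "direct" | "revcomp"
    length: int
    identity: float


@dataclass
class OriCandidate:
    interval: FeatureInterval
    hr_id: int | None
    at_fraction: float
    direct_repeats: list[DirectRepeatPair]
    tier: int  # 1 = full evidence triple; 2 = repeats + AT without hr context


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = np.array([3, 2, 1, 0, 5], dtype=np.int8)  # N complements to nothing


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(
        s.upper()
        .translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04"))
        .encode("latin1"),
        dtype=np.int8,
    ).copy()


def find_palindromes(g: Genome, min_arm: int = 15, max_loop: int = 40,
                     max_mismatch_rate: float = 0.2,
                     max_arm: int = 100) -> list[Palindrome]:
    """Maximal imperfect palindromes, reduced to best-scoring per locus.

    For every loop placement the longest arm with at most
    ``floor(arm * max_mismatch_rate)`` mismatches is found (N counts as
    mismatch); arms shorter than ``min_arm`` are dropped.  Overlapping
    calls are reduced greedily to the best (longest arm, fewest
    mismatches, smallest start).
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    n = g.length
    seq = g.sequence + g.sequence if g.is_circular else g.sequence
    x = _encode(seq)
    N = len(x)
    comp = _COMP[x]
    # mismatch vectors per pair distance d: v_d[p] = x[p] does not pair x[p+d]
    results: dict[tuple[int, int, int], tuple[int, int]] = {}
    for gap in range(0, max_loop + 1):
        mism = np.zeros(N, dtype=np.int32)
        best = np.zeros(N, dtype=np.int32)
        bestm = np.zeros(N, dtype=np.int32)
        for k in range(max_arm):
            # pair: x[l-1-k] vs comp of x[l+gap+k], contiguous in l
            lo = k + 1            # need l-1-k >= 0
            hi = N - gap - k      # need l+gap+k <= N-1  -> l < N-gap-k
            if lo >= hi:
                break
            left = x[lo - 1 - k : hi - 1 - k]
            right = comp[lo + gap + k : hi + gap + k]
            mism[lo:hi] += (left != right) | (left >= 4)
            mism[:lo] = 10 ** 6  # boundary: cannot reach this depth
            mism[hi:] = 10 ** 6
            a = k + 1
            if a >= min_arm:
                budget = int(math.floor(a * max_mismatch_rate))
                ok = np.nonzero(mism[lo:hi] <= budget)[0] + lo
                best[ok] = a
                bestm[ok] = mism[ok]
        found = np.nonzero(best)[0]
        for l in found:
            a = int(best[l])
            m = int(bestm[l])
            start0 = l - a          # 0-based leftmost
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
    pals: list[Palindrome] = []
    for (start0, span, gap), (a, m) in results.items():
        start0, span, gap = int(start0), int(span), int(gap)
        s1 = start0 + 1
        e1 = (start0 + span - 1) % n + 1 if g.is_circular else start0 + span
        iv = FeatureInterval(s1, e1 if e1 >= 1 else n, "+")
        seq_p = subsequence(g, iv)
        pals.append(
            Palindrome(interval=iv, arm_length=a, loop_length=gap,
                       mismatches=m, at_fraction=at_fraction(seq_p))
        )
    return _reduce_overlaps(pals, n, g.is_circular)


def _cover(iv: FeatureInterval, n: int) -> list[tuple[int, int]]:
    if iv.wraps_origin:
        return [(iv.start, n), (1, iv.end)]
    return [(iv.start, iv.end)]


def _overlaps(a: FeatureInterval, b: FeatureInterval, n: int) -> bool:
    for s1, e1 in _cover(a, n):
        for s2, e2 in _cover(b, n):
            if min(e1, e2) >= max(s1, s2):
                return True
    return False


def _reduce_overlaps(pals: list[Palindrome], n: int,
                     circular: bool) -> list[Palindrome]:
    ordered = sorted(
        pals, key=lambda p: (-p.arm_length, p.mismatches, p.interval.start)
    )
    kept: list[Palindrome] = []
    for p in ordered:
        if all(not _overlaps(p.interval, k.interval, n) for k in kept):
            kept.append(p)
    kept.sort(key=lambda p: p.interval.start)
    return kept


# ---------------------------------------------------------------------------
# hairpin free energy (nearest-neighbour approximation)
# ---------------------------------------------------------------------------

# Unified DNA nearest-neighbour stacking ΔG°37 (kcal/mol), 5'->3' top strand
NN_DELTA_G = {
    "AA": -1.00, "AT": -0.88, "TA": -0.58, "CA": -1.45, "GT": -1.44,
    "CT": -1.28, "GA": -1.30, "CG": -2.17, "GC": -2.24, "GG": -1.84,
    # complements
    "TT": -1.00, "TG": -1.45, "AC": -1.44, "AG": -1.28, "TC": -1.30,
    "CC": -1.84,
}

# hairpin-loop initiation penalties (kcal/mol) by loop size
LOOP_INIT = {3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.1, 8: 4.3, 9: 4.5, 10: 4.6}
MISMATCH_PENALTY = 1.0  # kcal/mol per mismatched stem pair
_RT37 = 0.616  # kcal/mol at 37 C


def _loop_penalty(size: int) -> float:
    size = max(size, 3)  # a hairpin loop cannot be shorter than 3 nt
    if size in LOOP_INIT:
        return LOOP_INIT[size]
    return LOOP_INIT[10] + 1.75 * _RT37 * math.log(size / 10)


def hairpin_delta_g(p: Palindrome, g: Genome) -> float:
    """Approximate hairpin folding ΔG (kcal/mol); more negative = stabler.

    Stacking free energy is summed over consecutive *matched* stem pairs;
    each mismatched pair interrupts stacking and adds a flat penalty; the
    loop contributes a size-dependent initiation term.
    """
    if p.arm_length < 2:
        raise ValueError("hairpin undefined for arm < 2")
    s = subsequence(g, p.interval)
    a, loop = p.arm_length, p.loop_length
    left = s[:a]
    right = s[-a:]
    # pair i: left[i] with right[a-1-i]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    paired = [
        left[i] != "N" and comp.get(left[i]) == right[a - 1 - i]
        for i in range(a)
    ]
    dg = _loop_penalty(loop)
    for i in range(a):
        if not paired[i]:
            dg += MISMATCH_PENALTY
    for i in range(a - 1):
        if paired[i] and paired[i + 1]:
            dg += NN_DELTA_G[left[i : i + 2]]
    return dg


# ---------------------------------------------------------------------------
# hr clustering and conserved ends
# ---------------------------------------------------------------------------

def cluster_hrs(pals: list[Palindrome], genome: Genome,
                max_gap: int = 1000) -> list[Hr]:
    """Single-linkage clustering of palindromes into hrs.

    Palindromes whose spans lie within ``max_gap`` nt of each other join
    one hr; on circular genomes adjacency across the origin is honoured.
    Hr ids are assigned clockwise from position 1.
    """
    if not pals:
        return []
    n = genome.length
    ordered = sorted(pals, key=lambda p: p.interval.start)
    clusters: list[list[Palindrome]] = [[ordered[0]]]
    for p in ordered[1:]:
        prev = clusters[-1][-1]
        prev_end = prev.interval.start + prev.span - 1  # linearised end
        gap = p.interval.start - prev_end - 1
        if gap <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    # circular wrap: last cluster may join the first through the origin
    if genome.is_circular and len(clusters) > 1:
        last = clusters[-1][-1]
        last_end = last.interval.start + last.span - 1
        first = clusters[0][0]
        wrap_gap = (n - last_end) + (first.interval.start - 1)
        if wrap_gap <= max_gap:
            clusters[0] = clusters.pop() + clusters[0]
    hrs = []
    for i, members in enumerate(
        sorted(clusters, key=lambda c: c[0].interval.start), start=1
    ):
        start = members[0].interval.start
        last = members[-1]
        end = (last.interval.start + last.span - 1 - 1) % n + 1
        hrs.append(
            Hr(id=i, interval=FeatureInterval(start, end, "+"),
               palindromes=members)
        )
    return hrs


def conserved_ends(pals: list[Palindrome], g: Genome, block_len: int = 15,
                   params: _align.AlignParams | None = None):
    """Consensus of the first/last ``block_len`` aligned palindrome columns.

    Aligns all palindrome sequences, extracts the flanking blocks, and
    reports whether the left flank is approximately the reverse
    complement of the right one (as expected for inverted-repeat ends).
    Returns ``(left_consensus, right_consensus, pfm, symmetric)``.
    """
    if len(pals) < 3:
        raise ValueError("conserved_ends needs at least 3 palindromes")
    seqs = [subsequence(g, p.interval) for p in pals]
    msa = _align.progressive_msa(seqs, params)
    pfm = _align.column_stats(msa)
    consensus = pfm.consensus()
    # flanks are read off the densely occupied columns only: a minority of
    # divergent cores can insert sparse columns inside the conserved ends
    n_rows = len(msa.rows)
    dense = [i for i, col in enumerate(pfm.columns)
             if sum(col.values()) >= 0.5 * n_rows]
    consensus = "".join(consensus[i] for i in dense)
    left = consensus[:block_len]
    right = consensus[-block_len:]
    rc_right = reverse_complement(right.replace("-", "N"))
    mismatches = sum(
        1 for a, b in zip(left, rc_right) if a != b or a in "N-"
    )
    symmetric = mismatches <= math.ceil(0.25 * block_len)
    return left, right, pfm, symmetric


# ---------------------------------------------------------------------------
# self similarity and direct repeats
# ---------------------------------------------------------------------------

def _seed_runs(sa: str, sb: str, k: int, same: bool,
               min_len: int, min_identity: float,
               b_offset: int = 0,
               chain_gap: int | None = None) -> list[tuple[int, int, int, int, float]]:
    """Greedy diagonal chaining of exact k-mer seeds between two strings.

    Returns (a_start0, a_end0, b_start0, b_end0, identity) with inclusive
    0-based ends; ``same`` suppresses the trivial self-diagonal.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(sb) - k + 1):
        index.setdefault(sb[j : j + k], []).append(j)
    # diagonal -> sorted seed starts
    diags: dict[int, list[int]] = {}
    for i in range(len(sa) - k + 1):
        for j in index.get(sa[i : i + k], ()):
            if same and i == j:
                continue
            diags.setdefault(j - i, []).append(i)
    if chain_gap is None:
        chain_gap = 2 * k
    hits = []
    for d, starts in diags.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:] + [None]:
            if i is not None and i - prev <= chain_gap:
                prev = i
                continue
            a0, a1 = run_start, prev + k - 1
            b0, b1 = a0 + d, prev + k - 1 + d
            length = a1 - a0 + 1
            if length >= min_len:
                matches = sum(
                    1 for t in range(length) if sa[a0 + t] == sb[b0 + t]
                )
                ident = 100.0 * matches / length
                if ident >= min_identity:
                    hits.append((a0, a1, b0 + b_offset, b1 + b_offset, ident))
            if i is not None:
                run_start = prev = i
    return hits


def self_similarity(g: Genome, min_len: int = 30, min_identity: float = 85.0,
                    k: int = 10) -> list[RepeatHit]:
    """Off-diagonal local matches of the genome against itself and its
    reverse complement (k-mer seeded, gap-free extension by chaining)."""
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    s = g.sequence
    hits: list[RepeatHit] = []
    seen = set()
    for a0, a1, b0, b1, ident in _seed_runs(s, s, k, True, min_len,
                                            min_identity):
        if b0 < a0:
            a0, a1, b0, b1 = b0, b1, a0, a1
        key = (a0, a1, b0, b1, "direct")
        if key in seen:
            continue
        seen.add(key)
        hits.append(
            RepeatHit(
                a=FeatureInterval(a0 + 1, a1 + 1, "+"),
                b=FeatureInterval(b0 + 1, b1 + 1, "+"),
                orientation="direct",
                length=a1 - a0 + 1,
                identity=ident,
            )
        )
    rc = reverse_complement(s)
    n = len(s)
    for a0, a1, b0, b1, ident in _seed_runs(s, rc, k, False, min_len,
                                            min_identity):
        # map rc coords back to forward: rc[j] = s[n-1-j]
        f1, f0 = n - 1 - b0, n - 1 - b1
        if f0 < a0:
            continue  # keep each inverted pair once (a left of b)
        key = (a0, a1, f0, f1, "revcomp")
        if key in seen:
            continue
        seen.add(key)
        hits.append(
            RepeatHit(
                a=FeatureInterval(a0 + 1, a1 + 1, "+"),
                b=FeatureInterval(f0 + 1, f1 + 1, "+"),
                orientation="revcomp",
                length=a1 - a0 + 1,
                identity=ident,
            )
        )
    hits.sort(key=lambda h: (h.a.start, h.b.start))
    return hits


def find_direct_repeats(region: FeatureInterval, g: Genome,
                        min_unit: int = 25, min_identity: float = 75.0,
                        k: int = 6) -> list[DirectRepeatPair]:
    """Same-orientation repeat pairs within a region, maximal and
    non-redundant.

    Every exact k-mer seed is kept (imperfect copies leave only short
    clean stretches), seeds are merged across drifting diagonals so
    gapped copies with different unit lengths chain into one pair, and
    identity is recomputed by global alignment of the two units.
    """
    s = subsequence(g, replace_strand(region, "+"))
    all_runs = _seed_runs(s, s, k, True, k, 0.0, chain_gap=4 * k)
    # only runs comfortably longer than k anchor a pair; isolated k-mers
    # are mostly noise in AT-rich sequence and would chain unrelated loci
    anchor_len = k + 4
    raw = [r for r in all_runs if r[1] - r[0] + 1 >= anchor_len]
    # merge chains whose diagonals drift (indels) by grouping overlapping
    # a-spans; keep each unordered pair once (a left of b)
    raw.sort(key=lambda h: (h[0], h[2]))
    # merge criterion: nearby a-span AND bounded diagonal drift (indels
    # shift the diagonal a little; unrelated seeds jump it)
    merged: list[list[int]] = []  # [a0, a1, b0, b1, dmin, dmax]
    for a0, a1, b0, b1, _ in raw:
        if b0 <= a0:
            continue
        d = b0 - a0
        placed = False
        for mrun in merged:
            if (a0 <= mrun[1] + 5 * k and a1 >= mrun[0] - 5 * k
                    and mrun[4] - 2 * k <= d <= mrun[5] + 2 * k):
                mrun[0] = min(mrun[0], a0)
                mrun[1] = max(mrun[1], a1)
                mrun[2] = min(mrun[2], b0)
                mrun[3] = max(mrun[3], b1)
                mrun[4] = min(mrun[4], d)
                mrun[5] = max(mrun[5], d)
                placed = True
                break
        if not placed:
            merged.append([a0, a1, b0, b1, d, d])
    # long clean per-diagonal runs stand on their own as candidates too —
    # a perfect tandem pair must not be diluted by nearby noisy merges
    candidates = [m[:4] for m in merged]
    candidates += [[a0, a1, b0, b1] for a0, a1, b0, b1, _ in raw
                   if a1 - a0 + 1 >= max(2 * k, min_unit // 2) and b0 > a0]
    scored = []
    offset = region.start - 1
    for a0, a1, b0, b1 in candidates:
        if b0 <= a1:
            # tandem run: one period on each side of the junction
            per = b0 - a0
            a1 = b0 - 1
            b1 = min(b1, b0 + per - 1)
            if a1 <= a0:
                continue
        ua, ub = a1 - a0 + 1, b1 - b0 + 1
        if max(ua, ub) < min_unit or min(ua, ub) < max(ua, ub) // 2:
            continue
        al = _align.global_align(s[a0 : a1 + 1], s[b0 : b1 + 1],
                                 _align.DNA_DEFAULT)
        # aligned-column identity penalises length-mismatched junk merges
        ident = _align.percent_identity(al, "aligned_columns")
        if ident < min_identity:
            continue
        scored.append((ident, a0, a1, b0, b1, ua, ub))
    # non-redundant: the longest above-threshold pair wins its locus
    # (identity breaks ties), so truncated sub-pairs never mask full ones
    scored.sort(key=lambda t: (-(t[5] + t[6]), -t[0], t[1], t[3]))
    out: list[DirectRepeatPair] = []
    taken: list[tuple[int, int, int, int]] = []
    for ident, a0, a1, b0, b1, ua, ub in scored:
        if any(min(a1, ta1) >= max(a0, ta0) and min(b1, tb1) >= max(b0, tb0)
               for ta0, ta1, tb0, tb1 in taken):
            continue
        taken.append((a0, a1, b0, b1))
        out.append(
            DirectRepeatPair(
                a=_offset_interval(a0, a1, offset, g.length),
                b=_offset_interval(b0, b1, offset, g.length),
                unit_length_a=ua,
                unit_length_b=ub,
                identity=ident,
            )
        )
    out.sort(key=lambda p: (p.a.start, p.b.start))
    return out


def replace_strand(iv: FeatureInterval, strand: str) -> FeatureInterval:
    return FeatureInterval(iv.start, iv.end, strand)


def _offset_interval(s0: int, e0: int, offset: int, n: int) -> FeatureInterval:
    s = (s0 + offset) % n + 1
    e = (e0 + offset) % n + 1
    return FeatureInterval(s, e, "+")


# ---------------------------------------------------------------------------
# non-hr ori flagging
# ---------------------------------------------------------------------------

def flag_non_hr_ori(g: Genome, hrs: list[Hr], at_threshold: float = 0.62,
                    pad: int = 600, min_pairs: int = 2, min_unit: int = 25,
                    min_identity: float = 72.0) -> list[OriCandidate]:
    """Flag ori-like regions by the evidence triple: AT-richness, >= 2
    direct-repeat pairs, and hr context (adjacent to / within an hr).

    Tier 1 candidates satisfy all three; AT-rich repeat regions without
    hr context are reported at tier 2.
    """
    n = g.length
    out: list[OriCandidate] = []
    hr_windows = []
    for hr in hrs:
        s = (hr.interval.start - 1 - pad) % n + 1
        e = (hr.interval.end - 1 + pad) % n + 1
        win = FeatureInterval(s, e, "+")
        hr_windows.append(win)
        pairs = find_direct_repeats(win, g, min_unit=min_unit,
                                    min_identity=min_identity)
        # AT evidence over the union of the hr envelope and the repeat
        # units themselves — intervening background does not dilute it
        cover: set[int] = set()
        core_s, core_e = hr.interval.start, hr.interval.end
        cover.update(hr.interval.positions(n))
        for pr in pairs:
            for iv2 in (pr.a, pr.b):
                cover.update(iv2.positions(n))
                core_s = min(core_s, iv2.start)
                core_e = max(core_e, iv2.end)
        bases = "".join(g.sequence[p - 1] for p in sorted(cover))
        frac = at_fraction(bases)
        if frac >= at_threshold and len(pairs) >= min_pairs:
            core = FeatureInterval(max(1, core_s),
                                   min(n, max(core_e, core_s)), "+")
            out.append(
                OriCandidate(interval=core, hr_id=hr.id, at_fraction=frac,
                             direct_repeats=pairs, tier=1)
            )
    # tier 2: repeat-dense AT-rich regions with no hr context
    hits = [h for h in self_similarity(g, min_len=min_unit,
                                       min_identity=min_identity)
            if h.orientation == "direct"]
    for h in hits:
        win = FeatureInterval(h.a.start, h.b.end if h.b.end >= h.a.start
                              else h.a.end, "+")
        if any(_overlaps(win, w, n) for w in hr_windows):
            continue
        frac = at_fraction(subsequence(g, win))
        pairs = find_direct_repeats(win, g, min_unit=min_unit,
                                    min_identity=min_identity)
        if frac >= at_threshold and len(pairs) >= min_pairs:
            out.append(
                OriCandidate(interval=win, hr_id=None, at_fraction=frac,
                             direct_repeats=pairs, tier=2)
            )
    return out
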