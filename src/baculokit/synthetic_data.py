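"""Synthetic genomes, protein families and ortholog orders with exact truth.

The generator emulates the architecture of a circular AT-rich
granulovirus-style genome: ATG-initiated ORF cassettes on both strands,
each preceded by a 150-nt promoter window engineered to carry exactly
the intended early/late motif configuration; AT-rich homologous-region
(hr) cassettes of 1-3 imperfect palindromes sharing a conserved 15-bp
inverted-repeat end block; and an optional ori-like cassette of direct
repeats adjacent to an hr.

After assembly the background is *scrubbed*: the package's own
detectors are run and any chance feature the background spawned
(spurious long ORF, spurious palindrome) is disrupted by a minimal,
constraint-checked point mutation, iterating to a fixed point.  The
result is a genome whose detector output equals the planted truth
exactly, which is what makes recall/precision assertions meaningful.

Every draw comes from one seeded generator, so a recipe + seed is
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import orf_caller, promoter_scan, repeat_finder
from .genome_io import Feature, FeatureInterval, Genome, reverse_complement
from .phylo import TreeNode, tip_names

__all__ = [
    "OrfCassette",
    "HrCassette",
    "OriCassette",
    "GenomeRecipe",
    "TruthTable",
    "PackingError",
    "make_genome",
    "default_recipe",
    "make_families",
    "make_ortholog_orders",
    "two_clade_tree",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

# conserved palindrome end block shared by all hr cassettes (15 bp, AT-rich
# with a distinctive anchor, mirroring tortricid-GV-style hr ends)
CONSERVED_END = "TTCGAGTGAGTTTTC"


class PackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class OrfCassette:
    aa_length: int = 150
    strand: str = "+"
    promoter: str = "none"  # early | late | both | none


@dataclass(frozen=True)
class HrCassette:
    """One hr: 1-3 palindromes of ``2*arm + loop`` bp.

    ``mismatches`` defaults to the full budget of the detector's default
    mismatch rate (floor(21 * 0.2) = 4) so a planted palindrome is
    maximal: any arm extension immediately exceeds the budget."""

    n_palindromes: int = 2
    arm: int = 21
    loop: int = 16
    mismatches: int = 4


@dataclass(frozen=True)
class OriCassette:
    tandem_unit: int = 31
    pair_lengths: tuple[int, int] = (79, 72)
    pair_identity: float = 0.85


@dataclass
class GenomeRecipe:
    """What to plant.  The defaults of :func:`default_recipe` express the
    study conditions (AT 58.5%, 16 hrs / 26 palindromes, mixed promoter
    classes); this bare dataclass is the low-level knob set."""

    length: int = 40_000
    at_target: float = 0.585
    orf_cassettes: list[OrfCassette] = field(default_factory=list)
    hr_cassettes: list[HrCassette] = field(default_factory=list)
    ori_cassette: OriCassette | None = None
    seed: int = 0
    hr_min_separation: int = 1_200  # keep distinct hrs > cluster max_gap apart
    max_retries: int = 1_000
    # palindrome-detector operating point the scrub guarantees truth for;
    # planted mismatches must equal floor(arm * detector_mismatch_rate)
    detector_min_arm: int = 15
    detector_mismatch_rate: float = 0.2


@dataclass
class TruthTable:
    """Planted features with exact intervals and classes."""

    orfs: list[dict] = field(default_factory=list)
    palindromes: list[dict] = field(default_factory=list)
    hrs: list[dict] = field(default_factory=list)
    ori: dict | None = None

    def to_features(self) -> list[Feature]:
        feats = []
        for i, o in enumerate(self.orfs, 1):
            feats.append(Feature(f"orf{i}", o["interval"], "CDS",
                                 {"promoter_class": o["promoter"]}))
        for i, p in enumerate(self.palindromes, 1):
            feats.append(Feature(f"pal{i}", p["interval"], "palindrome",
                                 {"hr": str(p["hr"]), "arm": str(p["arm"]),
                                  "loop": str(p["loop"]),
                                  "mismatches": str(p["mismatches"])}))
        for h in self.hrs:
            feats.append(Feature(f"hr{h['id']}", h["interval"],
                                 "homologous_region",
                                 {"n_palindromes": str(h["n_palindromes"])}))
        if self.ori:
            feats.append(Feature("ori1", self.ori["interval"], "ori_like", {}))
        return feats


def default_recipe(seed: int = 0, length: int = 40_000) -> GenomeRecipe:
    """The study-condition recipe: AT-rich circular genome, 30 ORFs with a
    mixed promoter-class census, 16 hrs holding 26 palindromes (1-3 per
    hr), and one ori-like direct-repeat cassette."""
    orfs = []
    classes = (["early"] * 6 + ["late"] * 8 + ["both"] * 4 + ["none"] * 12)
    rng = np.random.default_rng(seed + 101)
    for i, cls in enumerate(classes):
        aa = int(rng.integers(60, 220))
        strand = "+" if rng.random() < 0.55 else "-"
        orfs.append(OrfCassette(aa_length=aa, strand=strand, promoter=cls))
    # 16 hrs, palindrome multiplicities summing to 26 (1..3 each)
    multiplicities = [1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 3, 3]
    hrs = [HrCassette(n_palindromes=m) for m in multiplicities]
    return GenomeRecipe(length=length, at_target=0.585, orf_cassettes=orfs,
                        hr_cassettes=hrs, ori_cassette=OriCassette(),
                        seed=seed)


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------

def _rand_dna(rng, n: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _rand_codons(rng, n_aa: int, at: float) -> str:
    """n_aa sense codons, none a stop, none ATG-free constraint needed."""
    out = []
    while len(out) < n_aa:
        c = _rand_dna(rng, 3, at)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def _window_has(window: str, pattern: str) -> bool:
    return bool(promoter_scan.match_iupac(window, pattern))


def _repair_forbidden(rng, w: list[str], reserved: set[int],
                      motifs, max_steps: int = 400) -> bool:
    """Mutate bases until the window holds no promoter motif and no ATG.

    ``reserved`` positions (0-based) are spliced-in motif content and are
    never touched; a forbidden occurrence whose free positions are all
    reserved aborts the attempt.
    """
    forbidden = ["ATG", "TATAW", motifs.early_inr, motifs.late_inr]
    for _ in range(max_steps):
        s = "".join(w)
        hit = None
        for pat in forbidden:
            for off in promoter_scan.match_iupac(s, pat):
                span = range(off - 1, off - 1 + len(pat))
                if all(i in reserved for i in span):
                    continue  # part of a planted motif, leave it
                hit = (pat, span)
                break
            if hit:
                break
        if hit is None:
            return True
        pat, span = hit
        free = [i for i in span if i not in reserved]
        i = free[int(rng.integers(0, len(free)))]
        w[i] = "ACGT"[int(rng.integers(0, 4))]
    return False


def _make_window(rng, cls: str, motifs=promoter_scan.DEFAULT_MOTIFS,
                 at: float = 0.55, max_tries: int = 50) -> str:
    """A 150-nt window classifying exactly as ``cls`` by construction.

    A random draw is repaired until free of promoter motifs and of ATG
    (so the downstream ORF's canonical start stays the planted one),
    then the class's motifs are spliced in at randomised offsets.
    """
    W = motifs.window
    for _ in range(max_tries):
        w = list(_rand_dna(rng, W, at))
        reserved: set[int] = set()
        if cls in ("early", "both"):
            tata = "TATAAAT"
            t0 = int(rng.integers(5, 60))
            spacer = int(rng.integers(motifs.spacer_min + 2,
                                      motifs.spacer_max - 2))
            c0 = t0 + len(tata) - 1 + spacer  # CAKT start offset (1-based)
            w[t0 - 1 : t0 - 1 + len(tata)] = list(tata)
            w[c0 - 1 : c0 + 3] = list("CATT")
            reserved |= set(range(t0 - 1, t0 - 1 + len(tata)))
            reserved |= set(range(c0 - 1, c0 + 3))
        if cls in ("late", "both"):
            l0 = int(rng.integers(100, W - 6))
            w[l0 : l0 + 5] = list("TTAAG")
            reserved |= set(range(l0, l0 + 5))
        if not _repair_forbidden(rng, w, reserved, motifs):
            continue
        s = "".join(w)
        call = promoter_scan.classify(s, motifs)
        if call.call == cls:
            return s
    raise PackingError(f"could not build a clean {cls!r} promoter window")


def _make_orf_block(rng, cas: OrfCassette, at: float) -> tuple[str, int, int]:
    """Build window+CDS block on the coding strand.

    Returns (block, cds_offset, cds_len): the CDS starts at ``cds_offset``
    (0-based within the block) and runs ``cds_len`` nt including the stop.
    """
    window = _make_window(rng, cas.promoter, at=at)
    body = _rand_codons(rng, cas.aa_length - 1, at)
    stop = "TAA"
    cds = "ATG" + body + stop
    block = window + cds
    return block, len(window), len(cds)


def _make_palindrome(rng, cas: HrCassette, at: float = 0.75) -> str:
    """arm + loop + revcomp(arm) with planted mismatches.

    Mismatches sit at pair depths 2..5 (counted from the loop), never at
    the two innermost pairs nor in the conserved 15-bp ends; together
    with mismatching loop ends and the post-assembly extension-pair
    enforcement this guarantees no loop-shifted or arm-extended variant
    of the planted palindrome ties or beats it, so the detected span is
    exactly the planted one.
    """
    interior = cas.arm - len(CONSERVED_END)
    if cas.mismatches > max(0, interior - 2):
        raise PackingError(
            f"cannot place {cas.mismatches} mismatches in an interior of "
            f"{interior} (arm {cas.arm})"
        )
    arm = CONSERVED_END + _rand_dna(rng, interior, at)
    right = reverse_complement(arm)
    right_l = list(right)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    # right-arm index j is pair depth j; depths 0..interior-1 are the
    # random interior, 2.. keeps the two innermost pairs matched
    for depth in range(2, 2 + cas.mismatches):
        cur = right_l[depth]
        alts = [b for b in "ACGT" if b != cur]
        right_l[depth] = alts[int(rng.integers(0, len(alts)))]
    # loop whose end pairs cannot pair (kills smaller-loop variants)
    while True:
        loop = _rand_dna(rng, cas.loop, at)
        if all(loop[i] != comp[loop[-1 - i]]
               for i in range(min(3, cas.loop // 2))):
            break
    return arm + loop + "".join(right_l)


def _pack(rng, length: int, blocks: list[tuple[str, str, int]],
          hr_min_separation: int, max_retries: int) -> list[tuple[int, str, str, int]]:
    """Place blocks (kind, seq, margin) without overlap; returns
    (start0, kind, seq, index) placements.  hr/ori blocks additionally
    keep ``hr_min_separation`` bp apart from each other."""
    for _ in range(max_retries):
        placements = []
        occupied: list[tuple[int, int]] = []
        hr_spans: list[tuple[int, int]] = []
        ok = True
        order = list(range(len(blocks)))
        rng.shuffle(order)
        for bi in order:
            kind, seq, margin = blocks[bi]
            placed = False
            for _try in range(200):
                start = int(rng.integers(0, length - len(seq)))
                s, e = start - margin, start + len(seq) + margin
                if any(not (e < os or s > oe) for os, oe in occupied):
                    continue
                if kind in ("hr", "ori"):
                    # enforce separation on the circle, origin included
                    def circ_gap(s1, e1, s2_, e2_):
                        if not (e1 < s2_ or e2_ < s1):
                            return 0
                        d1 = (s2_ - e1) % length
                        d2 = (s1 - e2_) % length
                        return min(d1, d2)

                    me = (start, start + len(seq) - 1)
                    if any(circ_gap(me[0], me[1], os, oe) <= hr_min_separation
                           for os, oe in hr_spans):
                        continue
                    hr_spans.append(me)
                occupied.append((s, e))
                placements.append((start, kind, seq, bi))
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return placements
    raise PackingError("could not pack cassettes without overlap")


# ---------------------------------------------------------------------------
# scrubbing
# ---------------------------------------------------------------------------

def _feature_masks(length: int, truth: TruthTable) -> tuple[np.ndarray, np.ndarray]:
    """(hard, orf_cds) position masks.

    ``hard`` covers palindrome and ori-repeat bodies — never mutated.
    ``orf_cds`` covers planted CDS bodies — mutable only under the
    no-stop codon constraint.  Promoter windows are soft: mutable when
    the window re-validates afterwards.
    """
    hard = np.zeros(length, dtype=bool)
    orf_cds = np.zeros(length, dtype=bool)

    def protect(mask, iv: FeatureInterval) -> None:
        for s, e in _spans(iv, length):
            mask[s - 1 : e] = True

    for o in truth.orfs:
        protect(orf_cds, o["interval"])
    for p in truth.palindromes:
        protect(hard, p["interval"])
    if truth.ori:
        # only the repeat units are immutable; cassette spacers stay
        # scrubbable so chance palindromes in the AT-rich ori region can
        # be disrupted
        for iv in truth.ori.get("unit_intervals",
                                [truth.ori["interval"]]):
            protect(hard, iv)
    return hard, orf_cds


def _window_string(seq: list[str], iv: FeatureInterval, length: int) -> str:
    s = "".join(seq[p - 1] for p in iv.positions(length))
    if iv.strand == "-":
        s = reverse_complement(s)
    return s


def _windows_ok(seq: list[str], truth: TruthTable, length: int,
                touched: set[int]) -> bool:
    """Re-validate every planted window that overlaps ``touched``."""
    for o in truth.orfs:
        wiv = o["window_interval"]
        if not any(((p - 1) in touched) for p in wiv.positions(length)):
            continue
        w = _window_string(seq, wiv, length)
        if "ATG" in w:
            return False
        if promoter_scan.classify(w).call != o["promoter"]:
            return False
    return True


def _spans(iv: FeatureInterval, n: int) -> list[tuple[int, int]]:
    if iv.wraps_origin:
        return [(iv.start, n), (1, iv.end)]
    return [(iv.start, iv.end)]


def _same_interval(a: FeatureInterval, b: FeatureInterval) -> bool:
    return a.start == b.start and a.end == b.end and a.strand == b.strand


def _scrub(seq: list[str], truth: TruthTable, length: int, rng,
           min_aa: int = 50, max_rounds: int = 80,
           det_min_arm: int = 15, det_rate: float = 0.2) -> None:
    """Mutate background until detectors reproduce the truth exactly."""
    hard, orf_cds = _feature_masks(length, truth)
    # stop-codon insertion additionally avoids palindrome extension zones,
    # else _enforce_palindrome_maximality and _break_orf can oscillate
    ext_zone = np.zeros(length, dtype=bool)
    for p in truth.palindromes:
        iv = p["interval"]
        for q in range(iv.start - 14, iv.start):
            ext_zone[(q - 1) % length] = True
        for q in range(iv.end + 1, iv.end + 15):
            ext_zone[(q - 1) % length] = True
    protected = hard | orf_cds | ext_zone  # for stop-codon insertion

    planted_orfs = [o["interval"] for o in truth.orfs]
    planted_pals = [p["interval"] for p in truth.palindromes]
    for _round in range(max_rounds):
        # scrub mutations elsewhere can re-create an extension pairing;
        # re-assert maximality every round (idempotent when intact)
        _enforce_palindrome_maximality(seq, truth, length)
        g = Genome(id="scrub", sequence="".join(seq), topology="circular")
        dirty = False
        # spurious ORFs that would survive minimal-overlap selection
        cands = orf_caller.enumerate_candidates(g, min_aa=min_aa)
        planted_recs = [c for c in cands
                        if any(_same_interval(c.interval, p)
                               for p in planted_orfs)]
        selected = orf_caller.select_minimal_overlap(cands, length)
        for rec in selected:
            if any(_same_interval(rec.interval, p) for p in planted_orfs):
                continue
            if _break_orf(seq, rec, length, protected, truth):
                dirty = True
            else:
                raise PackingError("cannot disrupt a spurious ORF")
        if not dirty:
            pals = repeat_finder.find_palindromes(
                g, min_arm=det_min_arm, max_mismatch_rate=det_rate)
            for p in pals:
                if any(_same_interval(p.interval, t) for t in planted_pals):
                    continue
                if _break_palindrome(seq, p, length, hard, rng, truth,
                                     min_arm=det_min_arm, rate=det_rate):
                    dirty = True
                else:
                    raise PackingError("cannot disrupt a spurious palindrome")
        if not dirty:
            return
    raise PackingError("scrub did not converge")


def _break_orf(seq: list[str], rec, length: int, protected: np.ndarray,
               truth: TruthTable) -> bool:
    """Disrupt a spurious ORF without damaging any planted feature.

    Preferred fix: write a stop codon into an internal codon outside the
    hard-protected mask; a codon inside a promoter window is allowed if
    the window still classifies as planted afterwards.  Fallback:
    destroy the start codon the same way.
    """
    iv = rec.interval
    positions = list(iv.positions(length))
    if iv.strand == "-":
        positions = positions[::-1]  # coding order: 5' -> 3'
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def try_write(codon_pos: list[int], bases: str) -> bool:
        if any(protected[p - 1] for p in codon_pos):
            return False
        saved = [seq[p - 1] for p in codon_pos]
        for p, b in zip(codon_pos, bases):
            # coding base b sits at genome position p; on '-' the forward
            # strand stores its complement
            seq[p - 1] = b if iv.strand == "+" else comp[b]
        if _windows_ok(seq, truth, length, {p - 1 for p in codon_pos}):
            return True
        for p, b in zip(codon_pos, saved):
            seq[p - 1] = b
        return False

    for ci in range(1, len(positions) // 3 - 1):
        if try_write(positions[3 * ci : 3 * ci + 3], "TAA"):
            return True
    start = positions[0:3]
    if not any(protected[p - 1] for p in start):
        saved = seq[start[0] - 1]
        seq[start[0] - 1] = "C" if iv.strand == "+" else "G"
        if _windows_ok(seq, truth, length, {start[0] - 1}):
            return True
        seq[start[0] - 1] = saved
    return False


def _orf_codon_constraint(seq: list[str], pos0: int, new_base: str,
                          truth: TruthTable, length: int) -> bool:
    """True iff mutating ``pos0`` to ``new_base`` keeps every planted ORF
    intact: never touches a start/stop codon and never creates an
    in-frame stop."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for o in truth.orfs:
        iv = o["interval"]
        positions = list(iv.positions(length))
        if iv.strand == "-":
            positions = positions[::-1]
        try:
            k = positions.index(pos0 + 1)
        except ValueError:
            continue
        if k < 3 or k >= len(positions) - 3:
            return False  # start or stop codon
        ci = k // 3
        codon_pos = positions[3 * ci : 3 * ci + 3]
        codon = []
        for p in codon_pos:
            b = seq[p - 1] if p != pos0 + 1 else new_base
            codon.append(b if iv.strand == "+" else comp[b])
        if "".join(codon) in _STOPS:
            return False
    return True


def _break_palindrome(seq: list[str], pal, length: int,
                      protected: np.ndarray, rng,
                      truth: TruthTable,
                      min_arm: int = 15, rate: float = 0.2) -> bool:
    """Break pairing of a spurious palindrome by one point mutation.

    Mutations may fall inside planted ORF bodies or promoter windows as
    long as the planted feature re-validates afterwards; planted
    palindrome/ori positions are off limits (``protected``).
    """
    import math as _math

    iv = pal.interval
    positions = list(iv.positions(length))
    a = pal.arm_length
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    # pair at depth k (k = 0 innermost, beside the loop) joins left-arm
    # index a-1-k with its mirror
    def pair_matches(k: int) -> bool:
        i = a - 1 - k
        return seq[positions[i] - 1] == comp.get(seq[positions[-1 - i] - 1])

    def mism_upto(n_pairs: int) -> int:
        return sum(1 for k in range(n_pairs) if not pair_matches(k))

    # mutations needed so that every sub-arm >= min_arm blows its budget;
    # mutating innermost (depth < min_arm) pairs raises every arm's count
    slack = max(
        _math.floor(aa * rate) - mism_upto(aa) for aa in range(min_arm, a + 1)
    )
    needed = slack + 1
    done = 0
    for k in range(min(min_arm, a)):
        if done >= needed:
            break
        if not pair_matches(k):
            continue
        i = a - 1 - k
        p_left = positions[i]
        p_right = positions[-1 - i]
        for p_mut, p_other in ((p_left, p_right), (p_right, p_left)):
            if protected[p_mut - 1]:
                continue
            cur = seq[p_mut - 1]
            partner = seq[p_other - 1]
            choices = [b for b in "ACGT" if b != cur and b != comp[partner]]
            rng.shuffle(choices)
            mutated = False
            for b in choices:
                if not _orf_codon_constraint(seq, p_mut - 1, b, truth, length):
                    continue
                seq[p_mut - 1] = b
                if _windows_ok(seq, truth, length, {p_mut - 1}):
                    mutated = True
                    break
                seq[p_mut - 1] = cur
            if mutated:
                done += 1
                break
    return done >= needed


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _make_ori_seq(rng, oc: OriCassette,
                  at: float = 0.75,
                  max_tries: int = 80) -> tuple[str, list[tuple[int, int]]]:
    """Tandem A1/A2 unit pair plus imperfect B1/B2 pair.

    Returns (seq, unit offsets) where offsets are 0-based inclusive
    spans of A1, A2, B1, B2 within the cassette.  Draws are rejected
    while any chance palindrome lies fully inside the repeat units
    (units are immutable afterwards, so such a palindrome could never be
    scrubbed away).
    """
    for _ in range(max_tries):
        unit = _rand_dna(rng, oc.tandem_unit, at)
        b1 = _rand_dna(rng, oc.pair_lengths[0], at)
        b2l = list(b1)
        # one contiguous deletion (typical of repeat-copy divergence)
        # plus substitutions spread out so clean anchor stretches remain
        n_del = oc.pair_lengths[0] - oc.pair_lengths[1]
        if n_del > 0:
            dstart = int(rng.integers(20, len(b2l) - 20 - n_del))
            del b2l[dstart : dstart + n_del]
        # identity is aligned-column identity: deletions already count
        n_cols = oc.pair_lengths[0]
        n_sub = max(0, int(round((1 - oc.pair_identity) * n_cols)) - n_del)
        if n_sub > 0:
            step = len(b2l) / (n_sub + 1)
            for j in range(1, n_sub + 1):
                spos = min(len(b2l) - 1, int(j * step))
                b2l[spos] = {"A": "C", "C": "A", "G": "T",
                             "T": "G"}[b2l[spos]]
        mid = _rand_dna(rng, 40, at)
        spacer2 = _rand_dna(rng, 30, at)
        u = oc.tandem_unit
        seq = unit + unit + mid + b1 + spacer2 + "".join(b2l)
        b1_off = 2 * u + len(mid)
        b2_off = b1_off + len(b1) + len(spacer2)
        units = [(0, u - 1), (u, 2 * u - 1),
                 (b1_off, b1_off + len(b1) - 1),
                 (b2_off, b2_off + len(b2l) - 1)]
        unit_pos = {p for s0, e0 in units for p in range(s0, e0 + 1)}
        probe = Genome(id="ori_probe", sequence=seq, topology="linear")
        calls = repeat_finder.find_palindromes(probe)
        if all(
            any(p not in unit_pos
                for p in range(c.interval.start - 1, c.interval.end))
            for c in calls
        ):
            return seq, units
    raise PackingError("could not draw a scrubbable ori cassette")


def _build_once(recipe: GenomeRecipe, rng) -> tuple[Genome, TruthTable]:
    at = recipe.at_target
    blocks: list[tuple[str, str, int]] = []
    orf_meta: list[tuple[int, OrfCassette, int, int]] = []
    for cas in recipe.orf_cassettes:
        block, off, cds_len = _make_orf_block(rng, cas, at)
        if cas.strand == "-":
            # build on coding strand, store reverse-complemented
            blocks.append(("orf", reverse_complement(block), 8))
        else:
            blocks.append(("orf", block, 8))
        orf_meta.append((len(blocks) - 1, cas, off, cds_len))
    hr_meta: list[tuple[int, HrCassette, list[tuple[int, int]], int]] = []
    for hi, cas in enumerate(recipe.hr_cassettes):
        parts = []
        pal_offsets = []
        pos = 0
        for j in range(cas.n_palindromes):
            spacer = _rand_dna(rng, int(rng.integers(80, 200)), at + 0.1) \
                if j > 0 else ""
            parts.append(spacer)
            pos += len(spacer)
            pal = _make_palindrome(rng, cas)
            pal_offsets.append((pos, len(pal)))
            parts.append(pal)
            pos += len(pal)
        ori_off = -1
        if hi == 0 and recipe.ori_cassette is not None:
            # the ori-like cassette sits immediately beside the first hr so
            # the evidence triple (AT, repeats, hr context) holds
            spacer = _rand_dna(rng, 80, at + 0.1)
            parts.append(spacer)
            pos += len(spacer)
            ori_seq, ori_units = _make_ori_seq(rng, recipe.ori_cassette)
            ori_off = pos
            parts.append(ori_seq)
            pos += len(ori_seq)
        blocks.append(("hr", "".join(parts), 16))
        hr_meta.append((len(blocks) - 1, cas, pal_offsets, ori_off,
                        ori_units if ori_off >= 0 else None))

    placements = _pack(rng, recipe.length, blocks,
                       recipe.hr_min_separation, recipe.max_retries)
    seq = list(_rand_dna(rng, recipe.length, at))
    placed_at = {}
    for start0, kind, s, bi in placements:
        seq[start0 : start0 + len(s)] = list(s)
        placed_at[bi] = start0

    truth = TruthTable()
    for bi, cas, off, cds_len in orf_meta:
        start0 = placed_at[bi]
        block_len = 150 + cds_len
        if cas.strand == "+":
            cds_s = start0 + off + 1
            cds_e = cds_s + cds_len - 1
            iv = FeatureInterval(cds_s, cds_e, "+")
            win = FeatureInterval(start0 + 1, start0 + off, "+")
        else:
            # block was reverse complemented: window sits at the far end
            cds_e_f = start0 + (block_len - off)      # forward-coord end
            cds_s_f = cds_e_f - cds_len + 1
            iv = FeatureInterval(cds_s_f, cds_e_f, "-")
            win = FeatureInterval(cds_e_f + 1, start0 + block_len, "-")
        truth.orfs.append(
            {"interval": iv, "window_interval": win,
             "promoter": cas.promoter, "aa_length": cas.aa_length}
        )
    hr_id = 0
    for bi, cas, pal_offsets, ori_off, ori_units in hr_meta:
        hr_id += 1
        start0 = placed_at[bi]
        for (pal_off, pal_len) in pal_offsets:
            s = start0 + pal_off + 1
            truth.palindromes.append(
                {"interval": FeatureInterval(s, s + pal_len - 1, "+"),
                 "hr": hr_id, "arm": cas.arm, "loop": cas.loop,
                 "mismatches": cas.mismatches}
            )
        first = start0 + pal_offsets[0][0] + 1
        last = start0 + pal_offsets[-1][0] + pal_offsets[-1][1]
        truth.hrs.append(
            {"id": hr_id, "interval": FeatureInterval(first, last, "+"),
             "n_palindromes": cas.n_palindromes}
        )
        if ori_off >= 0:
            block_len = len(blocks[bi][1])
            truth.ori = {
                "interval": FeatureInterval(start0 + ori_off + 1,
                                            start0 + block_len, "+"),
                "hr_id": hr_id,
                "tandem_unit": recipe.ori_cassette.tandem_unit,
                "pair_lengths": recipe.ori_cassette.pair_lengths,
                "unit_intervals": [
                    FeatureInterval(start0 + ori_off + s0 + 1,
                                    start0 + ori_off + e0 + 1, "+")
                    for s0, e0 in ori_units
                ],
            }

    truth.orfs.sort(key=lambda o: o["interval"].start)
    truth.palindromes.sort(key=lambda p: p["interval"].start)

    _enforce_palindrome_maximality(seq, truth, recipe.length)
    _scrub(seq, truth, recipe.length, rng,
           det_min_arm=recipe.detector_min_arm,
           det_rate=recipe.detector_mismatch_rate)
    genome = Genome(id=f"synthetic_seed{recipe.seed}", sequence="".join(seq),
                    topology="circular")
    return genome, truth


def _enforce_palindrome_maximality(seq: list[str], truth: TruthTable,
                                   length: int, depth: int = 13) -> None:
    """Force the first ``depth`` arm-extension pairs of every planted
    palindrome to mismatch, so detected spans equal planted spans.

    ``depth`` covers every loop-shifted variant reachable within the
    detector's default loop ceiling ((max_loop - loop) / 2 for the
    default cassette), not just direct arm extensions."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for p in truth.palindromes:
        iv = p["interval"]
        for k in range(1, depth + 1):
            left = (iv.start - 1 - k) % length
            right = (iv.end - 1 + k) % length
            if seq[right] == comp.get(seq[left], "?"):
                for b in "TAGC":
                    if b != seq[right] and b != comp.get(seq[left], "?"):
                        seq[right] = b
                        break


def make_genome(recipe: GenomeRecipe) -> tuple[Genome, TruthTable]:
    """Assemble the genome and its exact truth table.

    Deterministic per (recipe, seed).  A handful of independent build
    attempts (derived deterministically from the seed) absorb rare
    unscrubbable layouts; :class:`PackingError` is raised only when all
    fail.
    """
    last: PackingError | None = None
    for attempt in range(6):
        rng = np.random.default_rng([recipe.seed, attempt])
        try:
            return _build_once(recipe, rng)
        except PackingError as exc:
            last = exc
    raise PackingError(f"all build attempts failed: {last}")


# ---------------------------------------------------------------------------
# protein family simulation
# ---------------------------------------------------------------------------

def two_clade_tree(n_per_clade: int = 4, depth: float = 0.5,
                   internal: float = 0.3) -> TreeNode:
    """A clock-like two-clade tree (clades 'a' and 'b'), tip height 0."""

    def clade(prefix: str) -> TreeNode:
        tips = [TreeNode(name=f"{prefix}{i + 1}") for i in range(n_per_clade)]
        # ladderize into a balanced-ish clock-like subtree
        height = depth - internal
        nodes = tips
        step = height / max(1, n_per_clade - 1)
        h = step
        while len(nodes) > 1:
            a = nodes.pop(0)
            b = nodes.pop(0)
            a.branch_length = h - a.height
            b.branch_length = h - b.height
            parent = TreeNode(children=[a, b], height=h)
            nodes.append(parent)
            h = min(height, h + step)
        nodes[0].height = height
        return nodes[0]

    left, right = clade("a"), clade("b")
    left.branch_length = depth - left.height
    right.branch_length = depth - right.height
    return TreeNode(children=[left, right], height=depth)


def _replacement_kernel() -> tuple[np.ndarray, dict[str, int]]:
    """A biased amino-acid replacement kernel (empirical-matrix flavoured)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    idx = {a: i for i, a in enumerate(_AA)}
    K = np.zeros((20, 20))
    for a in _AA:
        for b in _AA:
            if a == b:
                continue
            K[idx[a], idx[b]] = math.exp(float(mat[a, b]) / 2.0)
        K[idx[a]] /= K[idx[a]].sum()
    return K, idx


def make_families(tree: TreeNode, n_families: int = 10, root_len: int = 100,
                  gamma_shape: float = 2.25, seed: int = 0
                  ) -> dict[str, dict[str, str]]:
    """Evolve protein families along a tree with gamma-distributed site
    rates and Poisson substitution counts per branch.

    Returns {family: {taxon: sequence}}; sequences are gap-free and of
    equal length within a family (substitution-only model), so each
    family is aligned by construction.
    """
    rng = np.random.default_rng(seed)
    K, idx = _replacement_kernel()
    aa = np.array(list(_AA))
    total_bl = _total_branch_length(tree)
    if total_bl == 0:
        import warnings

        warnings.warn("tree has zero total branch length; taxa will be "
                      "identical to the root")
    out: dict[str, dict[str, str]] = {}
    for f in range(n_families):
        rates = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=root_len)
        root = rng.integers(0, 20, size=root_len)
        fam: dict[str, str] = {}

        def walk(node: TreeNode, state: np.ndarray) -> None:
            state = state.copy()
            if node.branch_length > 0:
                lam = node.branch_length * rates
                nsub = rng.poisson(lam)
                for site in np.nonzero(nsub)[0]:
                    cur = state[site]
                    for _ in range(int(nsub[site])):
                        cur = int(rng.choice(20, p=K[cur]))
                    state[site] = cur
            if node.is_leaf:
                fam[node.name] = "".join(aa[state])
            for c in node.children:
                walk(c, state)

        walk(tree, root)
        out[f"fam{f + 1}"] = fam
    return out


def _total_branch_length(tree: TreeNode) -> float:
    total = tree.branch_length

    def walk(n: TreeNode) -> float:
        return sum(c.branch_length + walk(c) for c in n.children)

    return total + walk(tree)


# ---------------------------------------------------------------------------
# ortholog orders
# ---------------------------------------------------------------------------

def make_ortholog_orders(n_genes: int = 60,
                         inversion: tuple[int, int, int] | None = (20, 18, 20_000),
                         gene_bp: int = 900, gap_bp: int = 150,
                         seed: int = 0):
    """Two genome gene orders, B = A with one segment reversed.

    ``inversion`` = (1-based start gene in A, gene count, target bp span);
    genes inside the inverted segment are sized so the segment totals the
    requested span.  Returns (order_a, order_b, spans_a, spans_b, truth).
    """
    rng = np.random.default_rng(seed)
    fams = [f"g{i + 1}" for i in range(n_genes)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in fams]
    order_a = list(zip(fams, strands))
    lengths = {f: gene_bp for f in fams}
    truth = {"inversion": None}
    if inversion is not None:
        start, count, span_bp = inversion
        seg = fams[start - 1 : start - 1 + count]
        per_gene = (span_bp - (count - 1) * gap_bp) // count
        for f in seg:
            lengths[f] = per_gene
        truth["inversion"] = {"families": seg, "span_bp": span_bp}
    spans_a = {}
    pos = 1
    for f in fams:
        spans_a[f] = (pos, pos + lengths[f] - 1)
        pos += lengths[f] + gap_bp
    order_b = list(order_a)
    if inversion is not None:
        start, count, _ = inversion
        seg = order_b[start - 1 : start - 1 + count]
        seg = [(f, "+" if s == "-" else "-") for f, s in reversed(seg)]
        order_b[start - 1 : start - 1 + count] = seg
    spans_b = {}
    pos = 1
    for f, _s in order_b:
        spans_b[f] = (pos, pos + lengths[f] - 1)
        pos += lengths[f] + gap_bp
    return order_a, order_b, spans_a, spans_b, truth
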