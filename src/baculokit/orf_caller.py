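"""ATG-initiated ORF enumeration on circular genomes and ORF-set selection.

Candidates are enumerated in all six frames; on circular genomes the
frames continue across the origin (implemented by scanning a doubled
sequence and deduplicating calls modulo the genome length).  Each
stop-to-stop segment contributes its 5'-most ATG — the longest possible
protein — as the canonical candidate; shorter in-frame starts are kept
in ``alt_starts``.  The final annotation set is chosen greedily,
longest first, under a cap on pairwise nucleotide overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import (
    FeatureInterval,
    Genome,
    reverse_complement,
    subsequence,
    translate,
)

__all__ = [
    "OrfRecord",
    "enumerate_candidates",
    "select_minimal_overlap",
    "number_from_anchor",
    "genome_stats",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfRecord:
    """A called ORF: genome interval, translation, and serial number.

    ``aa_length`` counts the initiator Met but not the stop; the
    nucleotide span is ``3 * (aa_length + 1)`` including the stop codon.
    ``alt_starts`` lists genome positions of shorter in-frame ATGs inside
    the same stop-to-stop segment.
    """

    interval: FeatureInterval
    aa_length: int
    protein: str = ""
    serial: int | None = None
    name: str | None = None
    alt_starts: list[int] = field(default_factory=list)

    def span_nt(self, genome_length: int | None = None) -> int:
        return self.interval.span(genome_length)


def _scan_oriented(seq: str, n: int, circular: bool, min_aa: int,
                   count_stop_in_min: bool) -> list[tuple[int, int, list[int]]]:
    """Scan the + strand of an oriented sequence for canonical ORFs.

    Returns (start0, aa_length, alt_start0s) with 0-based start positions
    on the oriented sequence, deduplicated modulo n for circular genomes.
    ORF = 5'-most ATG after the previous stop, ending at the next in-frame
    stop. min length: protein >= min_aa residues (or CDS+stop >= 3*min_aa
    when count_stop_in_min, the looser literal-150-nt reading).
    """
    s = seq + seq if circular else seq
    # CDS length including the stop codon; the "literal" reading counts the
    # stop toward the minimum (min 150 nt for 50 aa), the default does not.
    min_cds = 3 * min_aa if count_stop_in_min else 3 * (min_aa + 1)
    out: list[tuple[int, int, list[int]]] = []
    seen: set[tuple[int, int]] = set()
    for frame in range(3):
        atgs: list[int] = []
        # On a circle the segment containing the scan start may truncate a
        # segment that really begins before the origin; only segments opened
        # by an observed stop are genuine.  The doubled scan guarantees every
        # true segment (length <= n) is seen after a stop.
        stop_seen = not circular
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if codon == "ATG":
                atgs.append(i)
            elif codon in _STOPS:
                if atgs and stop_seen:
                    start = atgs[0]
                    cds_len = i + 3 - start  # includes stop
                    if cds_len >= min_cds and (not circular or cds_len <= n):
                        key = (start % n, (i + 2) % n)
                        if key not in seen:
                            seen.add(key)
                            out.append((start, cds_len // 3 - 1, atgs[1:]))
                atgs = []
                stop_seen = True
    return out


def enumerate_candidates(g: Genome, min_aa: int = 50,
                         count_stop_in_min: bool = False) -> list[OrfRecord]:
    """All canonical ATG-initiated ORF candidates on both strands.

    Internal-stop-free by construction.  Sorted by clockwise start
    position (then strand) for reproducibility.
    """
    if g.length < 3:
        raise ValueError("genome shorter than one codon")
    n = g.length
    records: list[OrfRecord] = []
    fwd = _scan_oriented(g.sequence, n, g.is_circular, min_aa, count_stop_in_min)
    for start0, aa_len, alts in fwd:
        cds_len = 3 * (aa_len + 1)
        start0 %= n
        start1 = start0 + 1
        end1 = (start0 + cds_len - 1) % n + 1
        iv = FeatureInterval(start1, end1, "+")
        prot = translate(_cds_seq(g, iv), strict=True)
        records.append(
            OrfRecord(interval=iv, aa_length=aa_len, protein=prot,
                      alt_starts=[(a % n) + 1 for a in alts])
        )
    rc = reverse_complement(g.sequence)
    rev = _scan_oriented(rc, n, g.is_circular, min_aa, count_stop_in_min)
    for start0, aa_len, alts in rev:
        cds_len = 3 * (aa_len + 1)
        # map oriented coords back: oriented position p (0-based) corresponds
        # to genome position n - (p % n) (1-based)
        g_start = n - (start0 % n)            # genome pos of ATG 'A' (1-based)
        g_end_0 = (start0 + cds_len - 1) % n  # oriented end
        g_end = n - g_end_0                   # genome pos of stop's last base
        iv = FeatureInterval(g_end, g_start, "-")
        prot = translate(_cds_seq(g, iv), strict=True)
        records.append(
            OrfRecord(interval=iv, aa_length=aa_len, protein=prot,
                      alt_starts=[n - (a % n) for a in alts])
        )
    records.sort(key=lambda r: (_clockwise_start(r, n), r.interval.strand))
    return records


def _cds_seq(g: Genome, iv: FeatureInterval) -> str:
    return subsequence(g, iv)


def _clockwise_start(r: OrfRecord, n: int) -> int:
    """Leftmost (clockwise-first) genome position of the ORF span."""
    iv = r.interval
    if iv.wraps_origin:
        return iv.start
    return iv.start


def _interval_cover(iv: FeatureInterval, n: int) -> list[tuple[int, int]]:
    """Unwrap to 1 or 2 linear [start, end] segments (1-based inclusive)."""
    if iv.wraps_origin:
        return [(iv.start, n), (1, iv.end)]
    return [(iv.start, iv.end)]


def _overlap_nt(a: FeatureInterval, b: FeatureInterval, n: int) -> int:
    total = 0
    for s1, e1 in _interval_cover(a, n):
        for s2, e2 in _interval_cover(b, n):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def select_minimal_overlap(cands: list[OrfRecord], genome_length: int,
                           max_overlap_nt: int = 75) -> list[OrfRecord]:
    """Greedy longest-first ORF selection under an overlap cap.

    A candidate is retained iff its nucleotide overlap with every
    already-retained ORF is at most ``max_overlap_nt`` (either strand).
    Length ties break by smaller start, then + strand.  The result is
    sorted by clockwise start.
    """
    n = genome_length
    ordered = sorted(
        cands,
        key=lambda r: (-r.aa_length, _clockwise_start(r, n),
                       0 if r.interval.strand == "+" else 1),
    )
    kept: list[OrfRecord] = []
    for c in ordered:
        if all(_overlap_nt(c.interval, k.interval, n) <= max_overlap_nt
               for k in kept):
            kept.append(c)
    kept.sort(key=lambda r: (_clockwise_start(r, n),
                             0 if r.interval.strand == "+" else 1))
    return kept


def number_from_anchor(orfs: list[OrfRecord], anchor: OrfRecord,
                       genome_length: int) -> list[OrfRecord]:
    """Rotate/reflect coordinates so the anchor starts at position 1 on +.

    The anchor's coding strand defines the clockwise orientation; serials
    1..n are then assigned in clockwise start order.  Applying the
    transform twice restores the original coordinates.
    """
    if anchor not in orfs:
        raise LookupError("anchor ORF not in the provided set")
    n = genome_length

    if anchor.interval.strand == "-":
        # reflect: genome position p -> n - p + 1, strands flip
        def tx(iv: FeatureInterval) -> FeatureInterval:
            s = n - iv.end + 1
            e = n - iv.start + 1
            strand = "+" if iv.strand == "-" else "-"
            return FeatureInterval(s, e, strand)
        reflected = [replace(o, interval=tx(o.interval)) for o in orfs]
        anchor = reflected[orfs.index(anchor)]
        orfs = reflected

    shift = anchor.interval.start - 1  # rotate left by this many bases

    def rot(iv: FeatureInterval) -> FeatureInterval:
        s = (iv.start - 1 - shift) % n + 1
        e = (iv.end - 1 - shift) % n + 1
        return FeatureInterval(s, e, iv.strand)

    rotated = [replace(o, interval=rot(o.interval)) for o in orfs]
    rotated.sort(key=lambda r: (_clockwise_start(r, n),
                                0 if r.interval.strand == "+" else 1))
    for i, o in enumerate(rotated, start=1):
        o.serial = i
    return rotated


def genome_stats(orfs: list[OrfRecord], g: Genome,
                 anchor_strand: str = "+") -> dict:
    """Summary of an ORF set: count, coding fraction, strand split, AT%.

    ``coding_fraction`` is the genome fraction covered by the union of
    ORF spans (overlaps counted once).
    """
    n = g.length
    covered = np.zeros(n, dtype=bool)
    same = opposite = 0
    for o in orfs:
        for s, e in _interval_cover(o.interval, n):
            covered[s - 1 : e] = True
        if o.interval.strand == anchor_strand:
            same += 1
        else:
            opposite += 1
    from .genome_io import at_fraction

    return {
        "n_orfs": len(orfs),
        "coding_fraction": float(covered.sum()) / n,
        "same_strand": same,
        "opposite_strand": opposite,
        "at_fraction": at_fraction(g),
    }
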