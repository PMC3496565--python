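"""Promoter motif scanning and early/late classification.

Each ORF's fixed-length upstream window (default 150 nt, on the coding
strand, circular wrap allowed) is scanned for degenerate IUPAC motifs:

* early: a TATA-box variant (TATAW, TATAWAW, TATAWTW) paired with a CAKT
  initiator starting 20-40 nt downstream of the TATA box end;
* late: the DTAAG initiator anywhere in the window;
* GATA (WGATAR / WGATAY): reported for information, never changing the call.

Offsets are 1-based from the window base farthest from the ATG.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_io import Genome
from .orf_caller import OrfRecord

__all__ = [
    "MotifSet",
    "MotifHit",
    "PromoterCall",
    "upstream_window",
    "match_iupac",
    "classify",
    "scan_all",
    "IUPAC_DNA",
]

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifSet:
    """The degenerate motifs and geometry used for classification."""

    early_tata: tuple[str, ...] = ("TATAWAW", "TATAWTW", "TATAW")
    early_inr: str = "CAKT"
    late_inr: str = "DTAAG"
    gata: tuple[str, ...] = ("WGATAR", "WGATAY")
    spacer_min: int = 20
    spacer_max: int = 40
    # spacer anchored at the TATA end by default; "start" measures from the
    # first TATA base instead
    spacer_anchor: str = "end"
    window: int = 150


DEFAULT_MOTIFS = MotifSet()


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    offset: int  # 1-based; 1 = window base farthest from the ATG
    text: str


@dataclass
class PromoterCall:
    orf_serial: int | None
    call: str  # early | late | both | none
    hits: list[MotifHit] = field(default_factory=list)


def upstream_window(g: Genome, orf: OrfRecord, window: int = 150) -> str:
    """The ``window`` nt immediately 5' of the start codon, coding strand.

    Wraps through the origin on circular genomes; on linear genomes the
    window truncates at the sequence end.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = g.length
    iv = orf.interval
    if iv.strand == "+":
        atg_pos = iv.start if not iv.wraps_origin else iv.start
        # 0-based index of the base just 5' of the ATG
        end0 = atg_pos - 1  # exclusive end in 0-based forward coords
        if g.is_circular:
            s2 = g.sequence + g.sequence
            start0 = end0 - window + n
            return s2[start0 : start0 + window]
        start0 = max(0, end0 - window)
        return g.sequence[start0:end0]
    # minus strand: the coding-strand upstream region lies 3' of iv.end on
    # the forward strand; take it and reverse-complement
    from .genome_io import reverse_complement

    atg_fwd0 = iv.end - 1 if not iv.wraps_origin else iv.end - 1
    start0 = atg_fwd0 + 1
    if g.is_circular:
        s2 = g.sequence + g.sequence
        return reverse_complement(s2[start0 : start0 + window])
    chunk = g.sequence[start0 : start0 + window]
    return reverse_complement(chunk)


def iupac_to_regex(pattern: str) -> str:
    parts = []
    for c in pattern.upper():
        if c not in IUPAC_DNA:
            raise ValueError(f"invalid IUPAC letter {c!r} in {pattern!r}")
        opts = IUPAC_DNA[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def match_iupac(window: str, pattern: str) -> list[int]:
    """All (overlapping) 1-based match offsets of an IUPAC pattern."""
    if not pattern:
        raise ValueError("empty pattern")
    rx = re.compile(f"(?=({iupac_to_regex(pattern)}))")
    return [m.start() + 1 for m in rx.finditer(window.upper())]


def classify(window: str, motifs: MotifSet = DEFAULT_MOTIFS,
             orf_serial: int | None = None) -> PromoterCall:
    """Classify one upstream window as early / late / both / none.

    Early requires a (TATA, CAKT) pair whose spacer — measured from the
    last TATA base to the first CAKT base, both excluded — puts the CAKT
    start 20-40 nt downstream (inclusive).  Late requires DTAAG anywhere.
    GATA hits are recorded but never change the call.
    """
    window = window.upper()
    hits: list[MotifHit] = []
    tata_spans: list[tuple[int, int, str]] = []  # (start, end, id) 1-based
    for pat in motifs.early_tata:
        for off in match_iupac(window, pat):
            tata_spans.append((off, off + len(pat) - 1, pat))
            hits.append(MotifHit(f"TATA:{pat}", off,
                                 window[off - 1 : off - 1 + len(pat)]))
    cakt_offs = match_iupac(window, motifs.early_inr)
    for off in cakt_offs:
        hits.append(MotifHit(f"INR:{motifs.early_inr}", off,
                             window[off - 1 : off - 1 + len(motifs.early_inr)]))
    late_offs = match_iupac(window, motifs.late_inr)
    for off in late_offs:
        hits.append(MotifHit(f"LATE:{motifs.late_inr}", off,
                             window[off - 1 : off - 1 + len(motifs.late_inr)]))
    for pat in motifs.gata:
        for off in match_iupac(window, pat):
            hits.append(MotifHit(f"GATA:{pat}", off,
                                 window[off - 1 : off - 1 + len(pat)]))

    early = False
    for (ts, te, _pat) in tata_spans:
        anchor = te if motifs.spacer_anchor == "end" else ts
        for c in cakt_offs:
            if motifs.spacer_min <= c - anchor <= motifs.spacer_max:
                early = True
                break
        if early:
            break
    late = bool(late_offs)
    call = ("both" if early and late
            else "early" if early
            else "late" if late
            else "none")
    hits.sort(key=lambda h: (h.offset, h.motif_id))
    return PromoterCall(orf_serial=orf_serial, call=call, hits=hits)


def scan_all(g: Genome, orfs: list[OrfRecord],
             motifs: MotifSet = DEFAULT_MOTIFS) -> tuple[list[PromoterCall], dict]:
    """One PromoterCall per ORF plus summary counts.

    The summary reports all conventions: ``n_early_any`` / ``n_late_any``
    count ORFs with the element regardless of the other class,
    ``n_early_only`` / ``n_late_only`` exclude dual-promoter ORFs, and
    ``n_both`` counts ORFs with both elements.
    """
    calls = []
    for o in orfs:
        w = upstream_window(g, o, motifs.window)
        calls.append(classify(w, motifs, orf_serial=o.serial))
    n_both = sum(1 for c in calls if c.call == "both")
    n_early_any = sum(1 for c in calls if c.call in ("early", "both"))
    n_late_any = sum(1 for c in calls if c.call in ("late", "both"))
    summary = {
        "n_early_any": n_early_any,
        "n_late_any": n_late_any,
        "n_both": n_both,
        "n_early_only": n_early_any - n_both,
        "n_late_only": n_late_any - n_both,
        "n_none": sum(1 for c in calls if c.call == "none"),
    }
    return calls, summary
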