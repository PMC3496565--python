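"""Gene-parity synteny: ortholog index pairs, colinear blocks, inversions.

A *gene parity plot* scatters the positional index of each shared gene
family in two genomes; colinear regions appear as diagonal runs and
inverted segments as anti-diagonal runs.  Blocks are chained greedily
from monotone runs with a bounded index gap, labelled forward or
inverted, and measured both in genes and in bp (from feature spans).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "ParityPoint",
    "SyntenyBlock",
    "parity_pairs",
    "colinear_blocks",
    "inversion_report",
]


@dataclass(frozen=True)
class ParityPoint:
    family: str
    index_a: int  # positional index (1-based) in genome A's clockwise order
    index_b: int
    strand_agreement: bool


@dataclass
class SyntenyBlock:
    orientation: str  # "forward" | "inverted"
    points: list[ParityPoint]
    span_bp_a: int = 0
    span_bp_b: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.points)


def parity_pairs(order_a: list[tuple[str, str]], order_b: list[tuple[str, str]],
                 shared_only: bool = True) -> list[ParityPoint]:
    """One point per shared family.

    ``order_a`` / ``order_b`` list (family id, strand) in each genome's
    clockwise gene order; families absent from either genome are skipped.
    """
    idx_b = {fam: (i + 1, strand) for i, (fam, strand) in enumerate(order_b)}
    points = []
    for i, (fam, strand_a) in enumerate(order_a, start=1):
        if fam in idx_b:
            j, strand_b = idx_b[fam]
            points.append(
                ParityPoint(family=fam, index_a=i, index_b=j,
                            strand_agreement=strand_a == strand_b)
            )
    if not points:
        warnings.warn("no shared families between the two genomes")
    return points


def colinear_blocks(points: list[ParityPoint],
                    max_index_gap: int = 2) -> list[SyntenyBlock]:
    """Greedy chaining of monotone runs into forward/inverted blocks.

    Points are processed in genome-A order; a point joins the current
    block if both index gaps are within ``max_index_gap`` and the B index
    moves in the block's direction.  Chaining is invariant to input
    order because points are sorted first.
    """
    if not points:
        return []
    pts = sorted(points, key=lambda p: p.index_a)
    blocks: list[SyntenyBlock] = []
    cur = [pts[0]]
    direction = 0  # 0 unknown, +1 forward, -1 inverted
    for p in pts[1:]:
        prev = cur[-1]
        da = p.index_a - prev.index_a
        db = p.index_b - prev.index_b
        step_dir = 1 if db > 0 else -1 if db < 0 else 0
        ok = (
            0 < da <= max_index_gap + 1
            and step_dir != 0
            and abs(db) <= max_index_gap + 1
            and (direction == 0 or step_dir == direction)
        )
        if ok:
            cur.append(p)
            if direction == 0:
                direction = step_dir
        else:
            blocks.append(_finish(cur, direction))
            cur = [p]
            direction = 0
    blocks.append(_finish(cur, direction))
    return blocks


def _finish(points: list[ParityPoint], direction: int) -> SyntenyBlock:
    orientation = "inverted" if direction < 0 else "forward"
    return SyntenyBlock(orientation=orientation, points=points)


def attach_spans(blocks: list[SyntenyBlock],
                 spans_a: dict[str, tuple[int, int]] | None,
                 spans_b: dict[str, tuple[int, int]] | None) -> None:
    """Fill bp spans from per-family (start, end) feature intervals."""
    for b in blocks:
        if spans_a:
            coords = [spans_a[p.family] for p in b.points if p.family in spans_a]
            if coords:
                b.span_bp_a = max(e for _, e in coords) - min(s for s, _ in coords) + 1
        if spans_b:
            coords = [spans_b[p.family] for p in b.points if p.family in spans_b]
            if coords:
                b.span_bp_b = max(e for _, e in coords) - min(s for s, _ in coords) + 1


def inversion_report(blocks: list[SyntenyBlock]) -> list[dict]:
    """Inverted blocks with gene counts and bp spans, largest first."""
    out = []
    for b in blocks:
        if b.orientation == "inverted" and b.n_genes >= 2:
            out.append(
                {
                    "n_genes": b.n_genes,
                    "span_bp_a": b.span_bp_a,
                    "span_bp_b": b.span_bp_b,
                    "families": [p.family for p in b.points],
                    "index_range_a": (b.points[0].index_a, b.points[-1].index_a),
                    "index_range_b": (
                        max(p.index_b for p in b.points),
                        min(p.index_b for p in b.points),
                    ),
                }
            )
    out.sort(key=lambda r: (-max(r["span_bp_a"], r["n_genes"]), r["index_range_a"]))
    return out
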