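"""Pairwise and progressive alignment plus position-frequency statistics.

Global pairwise alignment is Needleman–Wunsch with affine gaps; the
implementation delegates the dynamic programme to Biopython's
``PairwiseAligner`` and fixes a deterministic traceback (the first
alignment in Biopython's canonical enumeration order).  The progressive
multiple aligner builds a UPGMA guide tree from pairwise identity
distances and merges profiles in guide-tree order, which is sufficient
for the short, related sequences it is used on here (palindrome cores,
protein families).

Gap-cost convention: a gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align as _bioalign
from Bio.Align import substitution_matrices

__all__ = [
    "AlignParams",
    "Alignment",
    "PositionFrequencyMatrix",
    "global_align",
    "percent_identity",
    "progressive_msa",
    "column_stats",
    "DNA_DEFAULT",
    "PROTEIN_DEFAULT",
]

_DNA_ALPHABET = set("ACGTN")
_GAP = "-"


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for global alignment.

    ``matrix_name`` of ``"simple"`` uses match/mismatch scores; otherwise
    it names a Biopython substitution matrix (e.g. ``BLOSUM62``).
    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "simple"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 2.0
    gap_extend: float = 1.0


# Defaults mirroring common practice: simple DNA scores, BLOSUM62 with
# ClustalW-style pairwise gap penalties for proteins.
DNA_DEFAULT = AlignParams("simple", 1.0, -1.0, 2.0, 1.0)
# multiple alignment needs much stiffer gaps: averaged profile scores are
# small, so cheap gaps shred related sequences into gap confetti
DNA_MSA = AlignParams("simple", 2.0, -1.0, 10.0, 0.5)
PROTEIN_DEFAULT = AlignParams("BLOSUM62", gap_open=10.0, gap_extend=0.1)
# preset honouring the low-identity guide-tree settings some pipelines use
PROTEIN_BLOSUM30 = AlignParams("BLOSUM45", gap_open=10.0, gap_extend=0.1)


@dataclass
class Alignment:
    """Gapped rows of equal length plus the score that produced them."""

    rows: list[str]
    score: float
    matrix_name: str = "simple"
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(_GAP, "")


def _looks_like_dna(*seqs: str) -> bool:
    return all(set(s) <= _DNA_ALPHABET for s in seqs)


def _make_aligner(params: AlignParams) -> _bioalign.PairwiseAligner:
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix_name == "simple":
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    else:
        aligner.substitution_matrix = substitution_matrices.load(
            params.matrix_name
        )
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(a: str, b: str, params: AlignParams | None = None) -> Alignment:
    """Optimal global (Needleman–Wunsch) alignment with affine gaps.

    Deterministic: of all co-optimal tracebacks the first in Biopython's
    canonical order is returned, so output is bit-stable.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    a, b = a.upper(), b.upper()
    a_dna, b_dna = _looks_like_dna(a), _looks_like_dna(b)
    if a_dna != b_dna:
        raise ValueError("mixed alphabets: one sequence looks like DNA, the other not")
    if params is None:
        params = DNA_DEFAULT if a_dna else PROTEIN_DEFAULT
    aligner = _make_aligner(params)
    result = aligner.align(a, b)
    best = result[0]
    rows = [str(best[0]), str(best[1])]
    return Alignment(rows=rows, score=float(result.score),
                     matrix_name=params.matrix_name)


def percent_identity(al: Alignment, mode: str = "aligned_columns") -> float:
    """Percent identical residue pairs in a two-row alignment.

    ``mode`` picks the denominator: ``aligned_columns`` counts every
    column with at least one residue (gap-gap columns never count);
    ``shorter_seq`` divides by the shorter ungapped sequence length.
    """
    if len(al.rows) != 2:
        raise ValueError(f"percent_identity needs 2 rows, got {len(al.rows)}")
    r0, r1 = al.rows
    matches = sum(
        1 for x, y in zip(r0, r1) if x == y and x != _GAP
    )
    if mode == "aligned_columns":
        denom = sum(1 for x, y in zip(r0, r1) if not (x == _GAP and y == _GAP))
    elif mode == "shorter_seq":
        denom = min(len(r0.replace(_GAP, "")), len(r1.replace(_GAP, "")))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise ValueError("empty alignment")
    return 100.0 * matches / denom


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

def _pairwise_distance(a: str, b: str, params: AlignParams) -> float:
    al = global_align(a, b, params)
    return 1.0 - percent_identity(al, "aligned_columns") / 100.0


def _upgma_merge_order(d: np.ndarray) -> list[tuple[int, int]]:
    """Average-linkage merge order on a condensed-style square matrix.

    Returns (i, j) cluster-index pairs; new clusters take index n, n+1...
    Tie-break: smallest (i, j) pair.
    """
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j) = min(dist, key=lambda k: (dist[k], k))
        merges.append((i, j))
        members = active[i] + active[j]
        sizes = {k: len(v) for k, v in active.items()}
        new_d = {}
        for k in active:
            if k in (i, j):
                continue
            a = dist.get((min(i, k), max(i, k)))
            b = dist.get((min(j, k), max(j, k)))
            new_d[k] = (a * sizes[i] + b * sizes[j]) / (sizes[i] + sizes[j])
        del active[i], active[j]
        dist = {
            (x, y): v for (x, y), v in dist.items()
            if x not in (i, j) and y not in (i, j)
        }
        for k, v in new_d.items():
            dist[(min(k, nxt), max(k, nxt))] = v
        active[nxt] = members
        nxt += 1
    return merges


def _profile_score(col_a: dict[str, int], col_b: dict[str, int],
                   params: AlignParams,
                   matrix) -> float:
    """Expected pairwise substitution score between two profile columns."""
    total = 0.0
    na = sum(col_a.values())
    nb = sum(col_b.values())
    for x, cx in col_a.items():
        for y, cy in col_b.items():
            if matrix is not None:
                s = float(matrix[x, y])
            else:
                s = params.match if x == y else params.mismatch
            total += cx * cy * s
    return total / (na * nb)


def _align_profiles(prof_a: list[list[str]], prof_b: list[list[str]],
                    params: AlignParams) -> tuple[list[list[str]], list[list[str]]]:
    """Affine-gap global alignment of two profiles (lists of rows)."""
    matrix = (None if params.matrix_name == "simple"
              else substitution_matrices.load(params.matrix_name))
    cols_a = [
        {c: sum(1 for r in prof_a if r[i] == c)
         for c in {r[i] for r in prof_a} - {_GAP}}
        for i in range(len(prof_a[0]))
    ]
    cols_b = [
        {c: sum(1 for r in prof_b if r[i] == c)
         for c in {r[i] for r in prof_b} - {_GAP}}
        for i in range(len(prof_b[0]))
    ]
    # all-gap columns score 0 against anything
    n, m = len(cols_a), len(cols_b)
    go, ge = params.gap_open + params.gap_extend, params.gap_extend
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -go - ge * (j - 1)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        ca = cols_a[i - 1]
        for j in range(1, m + 1):
            s = (_profile_score(ca, cols_b[j - 1], params, matrix)
                 if ca and cols_b[j - 1] else 0.0)
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + s
            ptrM[i, j] = k
            opts = (M[i - 1, j] - go, X[i - 1, j] - ge)
            k = int(np.argmax(opts))
            X[i, j] = opts[k]
            ptrX[i, j] = k
            opts = (M[i, j - 1] - go, Y[i, j - 1] - ge)
            k = int(np.argmax(opts))
            Y[i, j] = opts[k]
            ptrY[i, j] = k
    # traceback; prefer M > X > Y on ties
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    ops = []  # 0 = column pair, 1 = gap in b, 2 = gap in a
    while i > 0 or j > 0:
        if i == 0:
            ops.append(2); j -= 1; continue
        if j == 0:
            ops.append(1); i -= 1; continue
        if state == 0:
            ops.append(0)
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append(1)
            state = int(ptrX[i, j])
            i -= 1
        else:
            ops.append(2)
            state = int(ptrY[i, j])
            j -= 1
    ops.reverse()
    new_a = [[] for _ in prof_a]
    new_b = [[] for _ in prof_b]
    ia = ib = 0
    for op in ops:
        if op == 0:
            for r, row in zip(prof_a, new_a):
                row.append(r[ia])
            for r, row in zip(prof_b, new_b):
                row.append(r[ib])
            ia += 1
            ib += 1
        elif op == 1:
            for r, row in zip(prof_a, new_a):
                row.append(r[ia])
            for row in new_b:
                row.append(_GAP)
            ia += 1
        else:
            for row in new_a:
                row.append(_GAP)
            for r, row in zip(prof_b, new_b):
                row.append(r[ib])
            ib += 1
    return new_a, new_b


def progressive_msa(seqs: list[str], params: AlignParams | None = None,
                    names: list[str] | None = None) -> Alignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Output row order equals input order.  Two sequences reduce to
    ``global_align``; a single sequence is returned unchanged.
    """
    if not seqs:
        raise ValueError("no sequences")
    seqs = [s.upper() for s in seqs]
    if params is None:
        params = DNA_MSA if _looks_like_dna(*seqs) else PROTEIN_DEFAULT
    names = names or [f"seq{i + 1}" for i in range(len(seqs))]
    if len(seqs) == 1:
        return Alignment(rows=list(seqs), score=0.0,
                         matrix_name=params.matrix_name, names=names)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_distance(seqs[i], seqs[j], params)
    merges = _upgma_merge_order(d)
    # cluster index -> (profile rows, original row indices)
    clusters: dict[int, tuple[list[list[str]], list[int]]] = {
        i: ([list(s)], [i]) for i, s in enumerate(seqs)
    }
    nxt = n
    score = 0.0
    for (i, j) in merges:
        pa, ixa = clusters.pop(i)
        pb, ixb = clusters.pop(j)
        na, nb = _align_profiles(pa, pb, params)
        clusters[nxt] = (na + nb, ixa + ixb)
        nxt += 1
    rows_lists, idx = clusters.popitem()[1]
    ordered = [None] * n
    for row, orig in zip(rows_lists, idx):
        ordered[orig] = "".join(row)
    return Alignment(rows=ordered, score=score,
                     matrix_name=params.matrix_name, names=names)


# ---------------------------------------------------------------------------
# position statistics
# ---------------------------------------------------------------------------

@dataclass
class PositionFrequencyMatrix:
    """Per-column symbol counts of an alignment plus information content."""

    columns: list[dict[str, int]]
    alphabet: list[str]
    info_bits: list[float]

    def consensus(self, threshold: float = 0.5) -> str:
        """Majority consensus; 'N'/'X' where no symbol reaches threshold."""
        unknown = "N" if set(self.alphabet) <= _DNA_ALPHABET else "X"
        out = []
        for col in self.columns:
            total = sum(col.values())
            if total == 0:
                out.append(_GAP)
                continue
            sym, cnt = max(sorted(col.items()), key=lambda kv: kv[1])
            out.append(sym if cnt / total >= threshold else unknown)
        return "".join(out)


def column_stats(al: Alignment) -> PositionFrequencyMatrix:
    """Counts, consensus support and information content per column.

    info = log2 |alphabet| + sum p log2 p, computed over non-gap symbols.
    """
    if len(al.rows) < 2:
        raise ValueError("column_stats needs >= 2 rows")
    symbols = sorted({c for r in al.rows for c in r} - {_GAP})
    is_dna = set(symbols) <= _DNA_ALPHABET
    alphabet = list("ACGT") if is_dna else symbols
    log_alpha = math.log2(len(alphabet)) if len(alphabet) > 1 else 0.0
    columns = []
    info = []
    for i in range(al.n_columns):
        col = {}
        for r in al.rows:
            c = r[i]
            if c != _GAP:
                col[c] = col.get(c, 0) + 1
        columns.append(col)
        total = sum(col.values())
        if total == 0:
            info.append(0.0)
            continue
        h = -sum((c / total) * math.log2(c / total) for c in col.values())
        info.append(max(0.0, log_alpha - h))
    return PositionFrequencyMatrix(columns=columns, alphabet=alphabet,
                                   info_bits=info)
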