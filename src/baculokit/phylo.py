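"""Concatenated core-gene distance phylogeny: UPGMA with gamma-corrected
distances and site bootstrap.

The default distance is the gamma-corrected Poisson transform
``d = a * ((1 - p)**(-1/a) - 1)`` of the proportion of differing sites
``p``, with gamma shape ``a`` (default 2.25) modelling among-site rate
variation; as ``a -> inf`` it reduces to the Poisson correction
``-ln(1 - p)``.  An "equal-input" variant using Dayhoff stationary
amino-acid frequencies is offered as an approximation to matrix-based
ML distances.

Columns are masked by *complete deletion* (any column with a gap in any
taxon is dropped) before distances are computed; the bootstrap resamples
supermatrix columns with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Supermatrix",
    "TreeNode",
    "DistanceModel",
    "mask_complete_deletion",
    "concatenate",
    "distance_matrix",
    "upgma",
    "bootstrap",
    "write_newick",
    "parse_newick",
    "tip_names",
    "bipartitions",
    "is_monophyletic",
]

_GAPS = set("-.?X*")

# Dayhoff amino-acid stationary frequencies (for the equal-input variant)
_DAYHOFF_FREQS = {
    "A": 0.087, "R": 0.041, "N": 0.040, "D": 0.047, "C": 0.033,
    "Q": 0.038, "E": 0.050, "G": 0.089, "H": 0.034, "I": 0.037,
    "L": 0.085, "K": 0.081, "M": 0.015, "F": 0.040, "P": 0.051,
    "S": 0.070, "T": 0.058, "W": 0.010, "Y": 0.030, "V": 0.065,
}


@dataclass(frozen=True)
class DistanceModel:
    """Distance transform: 'gamma_poisson' (default) or 'dayhoff_equal_input'.

    ``gamma_shape`` is the shape of the gamma law for among-site rate
    variation; None disables the correction (plain Poisson).
    """

    kind: str = "gamma_poisson"
    gamma_shape: float | None = 2.25

    def __post_init__(self) -> None:
        if self.kind not in ("gamma_poisson", "dayhoff_equal_input"):
            raise ValueError(f"unknown distance model {self.kind!r}")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


@dataclass
class Supermatrix:
    """Concatenated alignment columns keyed by taxon, plus gene boundaries."""

    taxa: list[str]
    rows: dict[str, str]
    boundaries: list[tuple[str, int, int]] = field(default_factory=list)
    # boundaries: (gene, first column 0-based, last column inclusive)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column_matrix(self) -> np.ndarray:
        return np.array([list(self.rows[t]) for t in self.taxa])


def mask_complete_deletion(rows: dict[str, str]) -> dict[str, str]:
    """Drop every column holding a gap/missing symbol in any taxon."""
    taxa = list(rows)
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError("rows are not aligned (unequal lengths)")
    arr = np.array([list(rows[t]) for t in taxa])
    bad = np.zeros(arr.shape[1], dtype=bool)
    for sym in _GAPS:
        bad |= (arr == sym).any(axis=0)
    keep = ~bad
    if not keep.any():
        raise ValueError("complete deletion removed every column")
    return {t: "".join(arr[i, keep]) for i, t in enumerate(taxa)}


def concatenate(alignments: list[dict[str, str]],
                gene_names: list[str] | None = None) -> Supermatrix:
    """Append gene alignments column-wise, matching rows by taxon id."""
    if not alignments:
        raise ValueError("no alignments")
    taxa = sorted(alignments[0])
    for i, al in enumerate(alignments):
        missing = set(taxa) ^ set(al)
        if missing:
            raise ValueError(
                f"gene {i} taxon set mismatch: {sorted(missing)}"
            )
    gene_names = gene_names or [f"gene{i + 1}" for i in range(len(alignments))]
    rows = {t: "" for t in taxa}
    boundaries = []
    col = 0
    for name, al in zip(gene_names, alignments):
        width = len(next(iter(al.values())))
        for t in taxa:
            rows[t] += al[t]
        boundaries.append((name, col, col + width - 1))
        col += width
    return Supermatrix(taxa=taxa, rows=rows, boundaries=boundaries)


def _p_distance(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        raise ValueError("sequences must be aligned and non-empty")
    diff = sum(1 for x, y in zip(a, b) if x != y)
    return diff / len(a)


def _transform(p: float, model: DistanceModel, pair: tuple[str, str]) -> float:
    if model.kind == "dayhoff_equal_input":
        b = 1.0 - sum(f * f for f in _DAYHOFF_FREQS.values())
        if p >= b:
            raise ValueError(f"saturated distance (p={p:.3f}) for pair {pair}")
        if model.gamma_shape is None:
            return -b * math.log(1.0 - p / b)
        a = model.gamma_shape
        return a * b * ((1.0 - p / b) ** (-1.0 / a) - 1.0)
    if p >= 1.0:
        raise ValueError(f"p = 1: infinite distance for pair {pair}")
    if model.gamma_shape is None:
        return -math.log(1.0 - p)
    a = model.gamma_shape
    return a * ((1.0 - p) ** (-1.0 / a) - 1.0)


def distance_matrix(sm: Supermatrix,
                    model: DistanceModel = DistanceModel()) -> np.ndarray:
    """Pairwise corrected distances over the supermatrix columns."""
    taxa = sm.taxa
    if len(taxa) < 2 or sm.n_columns < 1:
        raise ValueError("need >= 2 taxa and >= 1 column")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _p_distance(sm.rows[taxa[i]], sm.rows[taxa[j]])
            d[i, j] = d[j, i] = _transform(p, model, (taxa[i], taxa[j]))
    return d


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A rooted (ultrametric, for UPGMA) tree node."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0          # node height above the tips
    branch_length: float = 0.0   # to the parent
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


def tip_names(node: TreeNode) -> list[str]:
    if node.is_leaf:
        return [node.name]
    out = []
    for c in node.children:
        out.extend(tip_names(c))
    return out


def upgma(d: np.ndarray, taxa: list[str]) -> TreeNode:
    """Average-linkage agglomeration; merge height d/2; deterministic.

    Ties break on the lexicographically smallest pair of member-taxon
    name tuples, so taxon relabelling/permutation cannot change the
    topology among equally distant merges.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(taxa):
        raise ValueError("matrix/taxa size mismatch")
    if np.isnan(d).any() or (d < 0).any():
        raise ValueError("distance matrix has NaN or negative entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=t) for i, t in enumerate(taxa)
    }
    sizes = {i: 1 for i in range(len(taxa))}
    mins = {i: min(tip_names(nodes[i])) for i in nodes}
    dist = {
        (i, j): float(d[i, j])
        for i in range(len(taxa))
        for j in range(i + 1, len(taxa))
    }
    nxt = len(taxa)
    while len(nodes) > 1:
        (i, j) = min(
            dist, key=lambda k: (dist[k], min(mins[k[0]], mins[k[1]]),
                                 max(mins[k[0]], mins[k[1]]))
        )
        h = dist[(i, j)] / 2.0
        a, b = nodes.pop(i), nodes.pop(j)
        a.branch_length = h - a.height
        b.branch_length = h - b.height
        parent = TreeNode(children=sorted([a, b], key=lambda n: min(tip_names(n))),
                          height=h)
        new_d = {}
        for k in nodes:
            da = dist[(min(i, k), max(i, k))]
            db = dist[(min(j, k), max(j, k))]
            new_d[k] = (da * sizes[i] + db * sizes[j]) / (sizes[i] + sizes[j])
        dist = {
            (x, y): v for (x, y), v in dist.items()
            if x not in (i, j) and y not in (i, j)
        }
        for k, v in new_d.items():
            dist[(min(k, nxt), max(k, nxt))] = v
        sizes[nxt] = sizes.pop(i) + sizes.pop(j)
        mins[nxt] = min(mins.pop(i), mins.pop(j))
        nodes[nxt] = parent
        nxt += 1
    root = nodes.popitem()[1]
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial clades (internal-node tip sets) of a rooted tree.

    On ultrametric (rooted) trees clade identity is what the bootstrap
    scores; singletons and the full tip set are excluded.
    """
    all_tips = frozenset(tip_names(tree))
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> None:
        for c in node.children:
            tips = frozenset(tip_names(c))
            if 1 < len(tips) < len(all_tips):
                out.add(tips)
            walk(c)

    walk(tree)
    return out


def is_monophyletic(tree: TreeNode, group: set[str]) -> bool:
    """True if some clade's tip set equals ``group`` exactly."""
    target = frozenset(group)

    def walk(node: TreeNode) -> bool:
        tips = frozenset(tip_names(node))
        if tips == target:
            return True
        if not target <= tips:
            return False
        return any(walk(c) for c in node.children)

    return walk(tree)


def bootstrap(sm: Supermatrix, n_reps: int = 100, seed: int = 0,
              model: DistanceModel = DistanceModel()) -> tuple[TreeNode, dict]:
    """Site bootstrap on the concatenated columns.

    Rebuilds the UPGMA tree on each column resample and annotates the
    full-data tree's internal nodes with the percentage of replicates
    containing the same bipartition.  Returns (tree, support-by-split).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full_tree = upgma(distance_matrix(sm, model), sm.taxa)
    splits = bipartitions(full_tree)
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncol = sm.n_columns
    arr = sm.column_matrix()
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rows = {t: "".join(arr[i, idx]) for i, t in enumerate(sm.taxa)}
        rep_sm = Supermatrix(taxa=sm.taxa, rows=rows)
        try:
            rep_tree = upgma(distance_matrix(rep_sm, model), sm.taxa)
        except ValueError:
            continue  # saturated replicate
        rep_splits = bipartitions(rep_tree)
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}

    def annotate(node: TreeNode) -> None:
        if not node.is_leaf:
            tips = frozenset(tip_names(node))
            if tips in supports:
                node.support = supports[tips]
            for c in node.children:
                annotate(c)

    annotate(full_tree)
    return full_tree, supports


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path=None) -> str:
    """Newick with branch lengths; supports as internal node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.branch_length:.6g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){label}:{node.branch_length:.6g}"

    if tree.is_leaf:
        s = f"{tree.name};"
    else:
        inner = ",".join(fmt(c) for c in tree.children)
        label = "" if tree.support is None else f"{tree.support:g}"
        s = f"({inner}){label};"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def parse_newick(s: str) -> TreeNode:
    """Parse the Newick dialect written by ``write_newick``."""
    s = s.strip().rstrip(";")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                node.support = float(label)
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node.branch_length = float(s[start:pos])
        return node

    root = parse_node()

    def set_heights(node: TreeNode) -> float:
        if node.is_leaf:
            node.height = 0.0
            return 0.0
        hs = [set_heights(c) + c.branch_length for c in node.children]
        node.height = max(hs)
        return node.height

    set_heights(root)
    return root
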