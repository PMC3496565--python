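import math

import numpy as np
import pytest

from baculokit import phylo
from baculokit import synthetic_data as sd


def random_ultrametric_tree(ntax, rng):
    nodes = [phylo.TreeNode(name=f"t{i}") for i in range(ntax)]
    h = 0.0
    while len(nodes) > 1:
        h += float(rng.uniform(0.1, 1.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes.pop(int(j)), nodes.pop(int(i))
        a.branch_length = h - a.height
        b.branch_length = h - b.height
        nodes.append(phylo.TreeNode(children=[a, b], height=h))
    return nodes[0]


def ultrametric_matrix(tree):
    tips = phylo.tip_names(tree)
    D = {}

    def walk(n):
        if n.is_leaf:
            return {n.name}
        sets = [walk(c) for c in n.children]
        for x in range(len(sets)):
            for y in range(x + 1, len(sets)):
                for ta in sets[x]:
                    for tb in sets[y]:
                        D[frozenset((ta, tb))] = 2 * n.height
        out = set()
        for s in sets:
            out |= s
        return out

    walk(tree)
    M = np.zeros((len(tips), len(tips)))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i != j:
                M[i, j] = D[frozenset((a, b))]
    return tips, M


class TestMasking:
    def test_gap_free_unchanged(self):
        rows = {"a": "MKV", "b": "MKI"}
        assert phylo.mask_complete_deletion(rows) == rows

    def test_single_gap_removes_column(self):
        rows = {"a": "MK-VL", "b": "MKIVL", "c": "MKIVL"}
        out = phylo.mask_complete_deletion(rows)
        assert out == {"a": "MKVL", "b": "MKVL", "c": "MKVL"}

    def test_matches_per_column_scan(self):
        rng = np.random.default_rng(0)
        alpha = list("ACDEFG-")
        rows = {f"t{i}": "".join(rng.choice(alpha, size=60))
                for i in range(4)}
        try:
            out = phylo.mask_complete_deletion(rows)
        except ValueError:
            return
        keep = [j for j in range(60)
                if all(rows[t][j] != "-" for t in rows)]
        for t in rows:
            assert out[t] == "".join(rows[t][j] for j in keep)

    def test_all_removed_raises(self):
        with pytest.raises(ValueError):
            phylo.mask_complete_deletion({"a": "-K", "b": "M-"})


class TestConcatenate:
    def test_column_arithmetic(self):
        a = {"x": "MKVLWAACDE", "y": "MKILWAACDE"}
        b = {"x": "FFFFFFFFFF", "y": "YYYYYYYYYY"}
        sm = phylo.concatenate([a, b])
        assert sm.n_columns == 20
        assert sm.boundaries == [("gene1", 0, 9), ("gene2", 10, 19)]

    def test_rows_matched_by_taxon_not_position(self):
        a = {"x": "MK", "y": "MI"}
        b = {"y": "WW", "x": "FF"}
        sm = phylo.concatenate([a, b])
        assert sm.rows["x"] == "MKFF" and sm.rows["y"] == "MIWW"

    def test_missing_taxon_rejected(self):
        with pytest.raises(ValueError, match="taxon"):
            phylo.concatenate([{"x": "MK", "y": "MI"}, {"x": "FF"}])

    def test_boundaries_tile_columns(self):
        genes = [{"x": "A" * n, "y": "C" * n} for n in (3, 7, 2)]
        sm = phylo.concatenate(genes)
        spans = [(s, e) for _, s, e in sm.boundaries]
        assert spans[0][0] == 0 and spans[-1][1] == sm.n_columns - 1
        for (_, _, e1), (_, s2, _) in zip(sm.boundaries, sm.boundaries[1:]):
            assert s2 == e1 + 1


class TestDistances:
    def test_identical_rows_zero(self):
        sm = phylo.Supermatrix(taxa=["a", "b"],
                               rows={"a": "MKVL", "b": "MKVL"})
        d = phylo.distance_matrix(sm)
        assert d[0, 1] == 0.0

    def test_gamma_closed_form(self):
        assert phylo._transform(0.1, phylo.DistanceModel(gamma_shape=2.25),
                                ("a", "b")) == \
            pytest.approx(2.25 * (0.9 ** (-1 / 2.25) - 1))

    def test_poisson_limit(self):
        big = phylo.DistanceModel(gamma_shape=1e6)
        d = phylo._transform(0.1, big, ("a", "b"))
        assert abs(d - (-math.log(0.9))) / (-math.log(0.9)) < 1e-3

    def test_saturated_pair_named(self):
        sm = phylo.Supermatrix(taxa=["a", "b"],
                               rows={"a": "AAAA", "b": "CCCC"})
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            phylo.distance_matrix(sm)

    def test_equal_input_variant_finite_and_larger(self):
        m1 = phylo.DistanceModel()
        m2 = phylo.DistanceModel(kind="dayhoff_equal_input",
                                 gamma_shape=2.25)
        d1 = phylo._transform(0.2, m1, ("a", "b"))
        d2 = phylo._transform(0.2, m2, ("a", "b"))
        assert d2 > d1 > 0


class TestUpgma:
    def test_forced_topology_and_heights(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        t = phylo.upgma(d, ["A", "B", "C"])
        assert phylo.write_newick(t) == "((A:1,B:1):2,C:3);"

    def test_recovers_random_ultrametric_trees_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            ntax = int(rng.integers(4, 13))
            tree = random_ultrametric_tree(ntax, rng)
            tips, M = ultrametric_matrix(tree)
            rec = phylo.upgma(M, tips)
            assert phylo.bipartitions(rec) == phylo.bipartitions(tree)
            # heights too: max tip-to-root distance equals tree height
            assert rec.height == pytest.approx(tree.height)

    def test_invariant_to_taxon_permutation(self):
        rng = np.random.default_rng(4)
        tree = random_ultrametric_tree(8, rng)
        tips, M = ultrametric_matrix(tree)
        perm = list(rng.permutation(len(tips)))
        tips2 = [tips[i] for i in perm]
        M2 = M[np.ix_(perm, perm)]
        assert phylo.bipartitions(phylo.upgma(M, tips)) == \
            phylo.bipartitions(phylo.upgma(M2, tips2))

    def test_bad_matrix_rejected(self):
        with pytest.raises(ValueError):
            phylo.upgma(np.array([[0, -1], [-1, 0]], float), ["a", "b"])


class TestBootstrapAndNewick:
    def _sm(self, seed=3):
        tree = sd.two_clade_tree(3, 0.5, 0.35)
        fams = sd.make_families(tree, n_families=6, root_len=60, seed=seed)
        return phylo.concatenate(list(fams.values()))

    def test_clean_clades_high_support(self):
        sm = self._sm()
        _, sup = phylo.bootstrap(sm, n_reps=100, seed=5)
        for clade in (frozenset({"a1", "a2", "a3"}),
                      frozenset({"b1", "b2", "b3"})):
            assert sup[clade] >= 95

    def test_supports_in_range_and_seeded(self):
        sm = self._sm()
        _, s1 = phylo.bootstrap(sm, n_reps=50, seed=7)
        _, s2 = phylo.bootstrap(sm, n_reps=50, seed=7)
        assert s1 == s2
        assert all(0 <= v <= 100 for v in s1.values())

    def test_newick_roundtrip_with_supports(self):
        sm = self._sm()
        tree, _ = phylo.bootstrap(sm, n_reps=20, seed=1)
        back = phylo.parse_newick(phylo.write_newick(tree))
        assert phylo.bipartitions(back) == phylo.bipartitions(tree)
        sup = [n.support for n in _walk(back) if n.support is not None]
        assert sup  # supports survive the round trip

    def test_random_tree_roundtrip(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            tree = random_ultrametric_tree(int(rng.integers(4, 9)), rng)
            back = phylo.parse_newick(phylo.write_newick(tree))
            assert phylo.bipartitions(back) == phylo.bipartitions(tree)


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)
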